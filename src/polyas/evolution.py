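"""Phylostratum-level isoform-count distributions and polyploidization-altered triads.

Gene evolutionary age is an input table of phylostratum (PS) levels, PS1
(oldest, Cellular Organism) to PS14 (youngest, Triticum).  Polyploidization
analysis first selects triads whose diploid ancestors disagree strongly in
PSI (the dominant isoform differs among diploids), then asks whether each
polyploid subgenome drifted away from its matched diploid ancestor
(A<->DV, B<->SP, D<->TA) by more than the shift threshold, alpha-gated.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import SUBGENOME_ANCESTOR, STAGES

EVENT_BINS = ("1", "2", "3", "4", "5+")

PLOIDY_VARIETIES = {"tetraploid": ("CM", "ST"), "hexaploid": ("AC", "CS")}
PLOIDY_SUBGENOMES = {"tetraploid": ("A", "B"), "hexaploid": ("A", "B", "D")}


def ps_event_distribution(
    catalog: pd.DataFrame,
    eligible_events: pd.Index,
    ps: pd.Series,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Distribution of eligible AS events per gene within each PS level.

    Returns (distribution, per-gene event counts, number of genes excluded
    for lacking a PS level).  The distribution has one row per PS level with
    proportions over the event-count bins 1/2/3/4/5+ summing to 1; genes with
    zero eligible events are excluded.
    """
    sub = catalog.loc[catalog.index.isin(eligible_events)]
    counts = sub.groupby("gene_id").size()
    have_ps = counts.index.intersection(ps.index)
    n_missing = len(counts) - len(have_ps)
    counts = counts.loc[have_ps]
    binned = np.minimum(counts.to_numpy(), 5)
    levels = ps.loc[counts.index].to_numpy()
    table = pd.crosstab(
        pd.Series(levels, name="ps_level"),
        pd.Series([EVENT_BINS[b - 1] for b in binned], name="events_per_gene"),
    ).reindex(columns=list(EVENT_BINS), fill_value=0)
    table = table.reindex(range(1, 15), fill_value=0)
    totals = table.sum(axis=1)
    dist = table.div(totals.where(totals > 0), axis=0)
    dist["n_genes"] = totals
    return dist, counts, n_missing


def ps_young_old_trend(
    counts: pd.Series, ps: pd.Series, young=(13, 14), old=(1, 2, 3, 4, 5, 6)
) -> tuple[float, float, float]:
    """One-sided test that young genes carry more AS events per gene.

    Returns (mean events/gene young, mean old, one-sided Mann-Whitney p).
    """
    levels = ps.loc[counts.index]
    y = counts[levels.isin(young)].to_numpy()
    o = counts[levels.isin(old)].to_numpy()
    if len(y) == 0 or len(o) == 0:
        raise ValueError("no genes in the young or old PS strata")
    _, p = stats.mannwhitneyu(y, o, alternative="greater")
    return float(y.mean()), float(o.mean()), float(p)


def _diploid_psi(
    triads: pd.DataFrame, psi_stage_means: pd.DataFrame, subgenome: str
) -> pd.DataFrame:
    """Triads x stages replicate-mean PSI of the diploid ancestor carrying
    the given subgenome."""
    ancestor = SUBGENOME_ANCESTOR[subgenome]
    block = psi_stage_means[ancestor]
    return block.reindex(triads[f"event_{subgenome}"]).set_axis(triads.index, axis=0)


def diploid_divergent_candidates(
    triads: pd.DataFrame,
    psi_stage_means: pd.DataFrame,
    config: AnalysisConfig | None = None,
    ploidy: str = "hexaploid",
) -> pd.DataFrame:
    """Triads (or diads) whose diploid ancestors disagree by >= diploid_delta.

    The criterion is a maximum pairwise difference of diploid replicate-mean
    PSI of at least ``diploid_delta`` in at least one stage/tissue: DV vs SP
    for tetraploid polyploidization, all pairs of DV/SP/TA for hexaploid.
    """
    config = config or AnalysisConfig()
    subgenomes = PLOIDY_SUBGENOMES[ploidy]
    dip = {s: _diploid_psi(triads, psi_stage_means, s) for s in subgenomes}
    max_delta = None
    for a, b in itertools.combinations(subgenomes, 2):
        delta = (dip[a] - dip[b]).abs()
        max_delta = delta if max_delta is None else np.maximum(max_delta, delta)
    best = max_delta.max(axis=1, skipna=True)
    out = triads.copy()
    out["max_diploid_delta"] = best
    return out[best >= config.diploid_delta]


def polyploidization_altered(
    candidates: pd.DataFrame,
    psi_stage_means: pd.DataFrame,
    config: AnalysisConfig | None = None,
    ploidy: str = "hexaploid",
) -> pd.DataFrame:
    """Call polyploidization-altered subgenomes on candidate triads/diads.

    Per subgenome, the shift is the mean over stage-matched differences
    PSI(polyploid) - PSI(diploid ancestor), averaged over the two cultivars
    of the ploidy; significance is a two-sided Welch test pooling the
    per-(cultivar, stage) PSI values against the diploid per-stage values.
    ``altered_pattern`` concatenates exactly the subgenomes with
    |shift| > polyploid_shift and p < alpha ("none" when empty).  Subgenomes
    whose ancestor PSI is entirely missing are skipped and flagged.
    """
    config = config or AnalysisConfig()
    subgenomes = PLOIDY_SUBGENOMES[ploidy]
    varieties = PLOIDY_VARIETIES[ploidy]
    rows = []
    for tid, triad in candidates.iterrows():
        rec: dict = {"triad_id": tid, "skipped_subgenomes": ""}
        pattern = []
        for s in subgenomes:
            event = triad[f"event_{s}"]
            dip_vals = psi_stage_means[SUBGENOME_ANCESTOR[s]].loc[event].to_numpy(dtype=float)
            poly = np.vstack(
                [psi_stage_means[v].loc[event].to_numpy(dtype=float) for v in varieties]
            )
            ok = np.isfinite(dip_vals) & np.isfinite(poly).all(axis=0)
            if ok.sum() < 2:
                rec["skipped_subgenomes"] += s
                rec[f"shift_{s}"] = np.nan
                rec[f"p_{s}"] = np.nan
                continue
            shift_per_stage = poly[:, ok].mean(axis=0) - dip_vals[ok]
            shift = float(shift_per_stage.mean())
            _, p = stats.ttest_ind(poly[:, ok].ravel(), dip_vals[ok], equal_var=False)
            rec[f"shift_{s}"] = shift
            rec[f"p_{s}"] = float(p)
            if abs(shift) > config.polyploid_shift and p < config.alpha:
                pattern.append(s)
        rec["altered_pattern"] = "".join(pattern) if pattern else "none"
        rows.append(rec)
    cols = ["triad_id"]
    for s in subgenomes:
        cols += [f"shift_{s}", f"p_{s}"]
    cols += ["altered_pattern", "skipped_subgenomes"]
    return pd.DataFrame(rows, columns=cols).set_index("triad_id")


def shared_altered_across_ploidies(
    tetraploid_calls: pd.DataFrame,
    hexaploid_calls: pd.DataFrame,
    tetraploid_triads: pd.DataFrame,
    hexaploid_triads: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subgenome intersection of altered calls in tetraploid and hexaploid.

    Calls are joined on the A-subgenome event (shared between diads and
    triads); a subgenome is shared-altered when it appears in the altered
    pattern of both ploidies.
    """
    tet = tetraploid_calls.join(tetraploid_triads["event_A"]).set_index("event_A")
    hexa = hexaploid_calls.join(hexaploid_triads["event_A"]).set_index("event_A")
    shared_events = tet.index.intersection(hexa.index)
    rows = []
    for ev in shared_events:
        tp = tet.loc[ev, "altered_pattern"]
        hp = hexa.loc[ev, "altered_pattern"]
        both = sorted(
            set(tp if tp != "none" else "") & set(hp if hp != "none" else "")
        )
        if both:
            rows.append({"event_A": ev, "shared_subgenomes": "".join(both)})
    return pd.DataFrame(rows, columns=["event_A", "shared_subgenomes"]).set_index("event_A")
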