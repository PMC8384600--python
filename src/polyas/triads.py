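"""Homoeolog AS triads: chain-based 1:1:1 matching, splicing bias, dominance.

A triad is a 1:1:1 correspondence of the same AS event type across the A, B
and D subgenomes, found by lifting event intervals through pairwise chain
files and requiring a unique reciprocal overlap partner on each side.  The
within-triad PSI range (max - min of the three homoeolog PSIs) classifies
splicing bias into balanced / unbalanced / switched; relative abundances are
assigned to one of seven dominance groups by nearest ideal centroid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chain import ChainSet
from .config import AnalysisConfig

BIAS_CATEGORIES = ("balanced", "unbalanced", "switched")

#: dominance groups and their ideal relative-abundance centroids (A, B, D).
#: balanced first so that argmin tie-breaking favours it.
DOMINANCE_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "A_dominant": (1.0, 0.0, 0.0),
    "B_dominant": (0.0, 1.0, 0.0),
    "D_dominant": (0.0, 0.0, 1.0),
    "A_suppressed": (0.0, 0.5, 0.5),
    "B_suppressed": (0.5, 0.0, 0.5),
    "D_suppressed": (0.5, 0.5, 0.0),
}


def liftover(
    interval: tuple[str, int, int], chain_set: ChainSet, min_overlap_fraction: float = 0.5
) -> tuple[str, int, int, str] | None:
    """Map a genomic interval through a chain set (thin wrapper)."""
    chrom, start, end = interval
    return chain_set.liftover(chrom, start, end, min_overlap_fraction)


def _overlap_candidates(
    lifted: tuple[str, int, int], catalog: pd.DataFrame, etype: str, min_frac: float
) -> list[str]:
    chrom, lo, hi = lifted
    sub = catalog[(catalog["chrom"] == chrom) & (catalog["event_type"] == etype)]
    if sub.empty:
        return []
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    ov = np.minimum(ends, hi) - np.maximum(starts, lo)
    denom = np.minimum(ends - starts, hi - lo)
    frac = np.where(denom > 0, ov / denom, 0.0)
    return list(sub.index[frac >= min_frac])


def match_events(
    source: pd.DataFrame, target: pd.DataFrame, chains: ChainSet, config: AnalysisConfig
) -> dict[str, str]:
    """Unique reciprocal 1:1 matches from source-catalog to target-catalog events.

    An event pairs only when its lifted interval overlaps exactly one
    same-type target event, and that target event lifts back (through the
    inverted chains) onto exactly the original event.  One-to-many mappings
    on either side are rejected.
    """
    inv = chains.invert()
    out: dict[str, str] = {}
    for eid, row in source.iterrows():
        lifted = chains.liftover(
            row["chrom"], row["start"], row["end"], config.min_overlap_fraction
        )
        if lifted is None:
            continue
        cands = _overlap_candidates(lifted[:3], target, row["event_type"], config.min_overlap_fraction)
        if len(cands) != 1:
            continue
        partner = cands[0]
        prow = target.loc[partner]
        back = inv.liftover(
            prow["chrom"], prow["start"], prow["end"], config.min_overlap_fraction
        )
        if back is None:
            continue
        rcands = _overlap_candidates(back[:3], source, row["event_type"], config.min_overlap_fraction)
        if rcands == [eid]:
            out[eid] = partner
    return out


def build_triads(
    catalogs: dict[str, pd.DataFrame],
    chains: dict[str, ChainSet],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Build 1:1:1 AS triads (or 1:1 diads for tetraploid catalogs).

    ``catalogs`` maps subgenome letters to filtered event catalogs; ``chains``
    holds the pairwise chain sets keyed "AB", "AD" and (optionally) "BD".
    Triads are seeded from the A->B and A->D matches; the B->D chain serves as
    a consistency check (``bd_consistent``), which becomes a hard filter when
    ``config.require_all_chains`` is set.  With no D catalog, A-B diads are
    returned instead.
    """
    config = config or AnalysisConfig()
    if "A" not in catalogs or "B" not in catalogs:
        raise ValueError("catalogs for subgenomes A and B are required")
    ab = match_events(catalogs["A"], catalogs["B"], chains["AB"], config)
    rows = []
    if "D" in catalogs:
        ad = match_events(catalogs["A"], catalogs["D"], chains["AD"], config)
        bd = (
            match_events(catalogs["B"], catalogs["D"], chains["BD"], config)
            if "BD" in chains
            else None
        )
        for ea, eb in ab.items():
            ed = ad.get(ea)
            if ed is None:
                continue
            consistent = bd.get(eb) == ed if bd is not None else True
            if config.require_all_chains and not consistent:
                continue
            rows.append(
                {
                    "triad_id": f"triad_{len(rows):04d}",
                    "event_A": ea, "event_B": eb, "event_D": ed,
                    "gene_A": catalogs["A"].loc[ea, "gene_id"],
                    "gene_B": catalogs["B"].loc[eb, "gene_id"],
                    "gene_D": catalogs["D"].loc[ed, "gene_id"],
                    "event_type": catalogs["A"].loc[ea, "event_type"],
                    "bd_consistent": consistent,
                }
            )
    else:
        for ea, eb in ab.items():
            rows.append(
                {
                    "triad_id": f"diad_{len(rows):04d}",
                    "event_A": ea, "event_B": eb,
                    "gene_A": catalogs["A"].loc[ea, "gene_id"],
                    "gene_B": catalogs["B"].loc[eb, "gene_id"],
                    "event_type": catalogs["A"].loc[ea, "event_type"],
                }
            )
    columns = (
        ["triad_id", "event_A", "event_B", "event_D", "gene_A", "gene_B", "gene_D",
         "event_type", "bd_consistent"]
        if "D" in catalogs
        else ["triad_id", "event_A", "event_B", "gene_A", "gene_B", "event_type"]
    )
    return pd.DataFrame(rows, columns=columns).set_index("triad_id")


def classify_triad_bias(psi_triples: np.ndarray, config: AnalysisConfig | None = None) -> np.ndarray:
    """Categorize within-triad PSI ranges into balanced/unbalanced/switched.

    ``psi_triples`` is (n, 3); half-open category boundaries
    [0, balanced_max) / [balanced_max, switched_min) / [switched_min, 100].
    Rows with any NA get the category ``"undefined"``.
    """
    config = config or AnalysisConfig()
    triples = np.atleast_2d(np.asarray(psi_triples, dtype=float))
    rng = triples.max(axis=1) - triples.min(axis=1)
    out = np.where(
        rng < config.balanced_max,
        "balanced",
        np.where(rng < config.switched_min, "unbalanced", "switched"),
    ).astype(object)
    out[np.isnan(triples).any(axis=1)] = "undefined"
    return out


def triad_psi_table(
    triads: pd.DataFrame,
    stage_means: pd.DataFrame,
    varieties: tuple[str, ...] = ("AC", "CS"),
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-(triad, variety, stage) homoeolog PSI triple, range and category.

    ``stage_means`` is the replicate-mean PSI matrix from
    :func:`polyas.psi.stage_mean_psi` (events x (variety, stage)).
    """
    config = config or AnalysisConfig()
    members = [c for c in ("event_A", "event_B", "event_D") if c in triads.columns]
    rows = []
    for variety in varieties:
        block = stage_means[variety]
        for stage in block.columns:
            vals = np.column_stack(
                [block[stage].reindex(triads[m]).to_numpy() for m in members]
            )
            cats = classify_triad_bias(vals, config)
            for i, tid in enumerate(triads.index):
                row = {"triad_id": tid, "variety": variety, "stage_tissue": stage}
                for j, m in enumerate(members):
                    row[f"psi_{m[-1]}"] = vals[i, j]
                row["psi_range"] = np.nanmax(vals[i]) - np.nanmin(vals[i]) if not np.isnan(vals[i]).any() else np.nan
                row["category"] = cats[i]
                rows.append(row)
    return pd.DataFrame(rows)


def assign_dominance(triples: np.ndarray) -> np.ndarray:
    """Assign relative-abundance triples to the seven dominance groups.

    Each (A, B, D) triple of non-negative values is normalized to fractions
    and mapped to the nearest ideal centroid by Euclidean distance, ties
    broken toward balanced.  Zero-sum rows yield ``"undefined"``.
    """
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    if triples.shape[1] != 3:
        raise ValueError("expected (n, 3) triples")
    sums = triples.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = triples / sums[:, None]
    centroids = np.array(list(DOMINANCE_CENTROIDS.values()))
    names = np.array(list(DOMINANCE_CENTROIDS.keys()), dtype=object)
    d2 = ((frac[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    out = names[np.nanargmin(np.where(np.isnan(d2), np.inf, d2), axis=1)].astype(object)
    out[(sums <= 0) | np.isnan(sums) | np.isnan(frac).any(axis=1)] = "undefined"
    return out


def ternary_coordinates(triples: np.ndarray) -> np.ndarray:
    """Normalize (A, B, D) triples to ternary fractions summing to 1."""
    triples = np.atleast_2d(np.asarray(triples, dtype=float))
    sums = triples.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("ternary coordinates undefined for zero-sum triples")
    return triples / sums[:, None]


def ge_dominance_table(
    triads: pd.DataFrame,
    gene_stage_means: pd.DataFrame,
    varieties: tuple[str, ...] = ("AC", "CS"),
) -> pd.DataFrame:
    """Per-(triad, variety, stage) GE dominance group from homoeolog gene TPM."""
    rows = []
    for variety in varieties:
        block = gene_stage_means[variety]
        for stage in block.columns:
            vals = np.column_stack(
                [block[stage].reindex(triads[f"gene_{s}"]).to_numpy() for s in "ABD"]
            )
            groups = assign_dominance(vals)
            rows.extend(
                {
                    "triad_id": tid,
                    "variety": variety,
                    "stage_tissue": stage,
                    "dominance_ge": groups[i],
                }
                for i, tid in enumerate(triads.index)
            )
    return pd.DataFrame(rows)


def balanced_ge_biased_as(
    bias_table: pd.DataFrame, dominance_ge: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triads with balanced gene expression but biased splicing.

    Joins the per-stage AS bias table with the per-stage GE dominance table
    and keeps rows where GE is balanced while the AS category is unbalanced
    or switched.  Also returns the (triad, variety) pairs that satisfy the
    condition at all seven embryo stages.
    """
    merged = bias_table.merge(dominance_ge, on=["triad_id", "variety", "stage_tissue"])
    kept = merged[
        (merged["dominance_ge"] == "balanced")
        & merged["category"].isin(["unbalanced", "switched"])
    ].copy()
    embryo = kept[kept["stage_tissue"].str[1:].astype(int) <= 7]
    counts = embryo.groupby(["triad_id", "variety"]).size()
    consistent = counts[counts == 7].reset_index()[["triad_id", "variety"]]
    return kept, consistent
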