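"""Synthetic grain-development dataset with planted ground truth.

The generator emulates the sampling design the analyses assume — 7 wheat and
grass varieties (hexaploid AC/CS, tetraploid CM/ST, diploid ancestors
DV=AA, SP=BB, TA=DD), 10 stage/tissue classes E01-E10 and 2 replicates —
and emits homoeologous triad gene models with multiple isoforms per locus,
their AS events, the pairwise subgenome chain files, transcript TPMs, and a
truth object recording every planted structure.

Construction principles:

* every triad gene has homoeologs on 1A/1B/1D whose coordinates are related
  by the emitted colinear chains, so chain liftover recovers the planted
  1:1:1 correspondences exactly;
* homoeolog PSI surfaces are driven by a per-stage within-triad spread drawn
  inside class-preserving bands (balanced/unbalanced/switched), wider in the
  early embryo (E01-E03) than the late embryo (E04-E07) to plant larger
  inter-subgenome splicing divergence early in embryogenesis;
* polyploid PSI surfaces copy the diploid ancestral surfaces except where a
  polyploidization alteration, cultivar difference or group-specific shift
  is planted, making the corresponding detectors' nulls exact;
* transcript TPMs are gene TPM x the isoform fractions implied by PSI (the
  inclusion form takes PSI/100 of the event-local mass, the remainder spread
  over the other isoforms), with a per-(gene, sample) multiplicative
  lognormal replicate factor — which cancels in every PSI ratio — and
  additive Gaussian PSI noise clipped to [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import Chain, ChainSet, write_chain
from .config import SimulationConfig
from .io import (
    EVENT_TYPES,
    STAGES,
    VARIETIES,
    TranscriptQuant,
    make_event_id,
    make_sample_table,
    write_gtf,
    write_ioe,
    write_ps_table,
    write_quant_table,
    write_samples,
)
from .triads import assign_dominance

SUBGENOMES = ("A", "B", "D")
CHROMS = {"A": "1A", "B": "1B", "D": "1D"}

GENE_SPACING = 2500
GENE_LENGTH = 2000
EVENT_LENGTH = 40
PRIMARY_OFFSET = 100
#: per-subgenome offsets for the extra (non-triad) events; staggered so that
#: lifted extras never reach the 50% reciprocal-overlap threshold.
EXTRA_OFFSET = {"A": 1200, "B": 1260, "D": 1230}
EXTRA_SPACING = 100

_WIDE = (0, 1, 2)      # E01-E03
_NARROW = (3, 4, 5, 6)  # E04-E07
_MID = (7, 8, 9)        # E08-E10

ROLES = (
    "plain", "conserved_ge", "altered", "ploidy_specific",
    "e01_specific", "e07_specific", "endosperm_specific", "cultivar_divergent",
)


@dataclass
class PlantedTruth:
    """Ground truth of the simulated dataset.

    ``triads`` has one row per planted triad (events, genes, planted class,
    role, alteration patterns, PS level, GE skew, diploid-candidate flag);
    ``psi_true`` is the noiseless event x sample PSI surface; ``bias_true``
    and ``dominance_true`` are the realized per-stage splicing-bias and GE
    dominance labels derived from the noiseless surfaces.
    """

    triads: pd.DataFrame
    psi_true: pd.DataFrame
    bias_true: pd.DataFrame
    dominance_true: pd.DataFrame


@dataclass
class SimulatedDataset:
    quant: TranscriptQuant
    samples: pd.DataFrame
    catalog: pd.DataFrame
    chains: dict[str, ChainSet]
    ps: pd.Series
    truth: PlantedTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# helpers

def _assign_roles(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_triads
    order = rng.permutation(n)
    roles = np.array(["plain"] * n, dtype=object)
    patterns = np.array([""] * n, dtype=object)
    ptr = 0

    def take(k):
        nonlocal ptr
        idx = order[ptr:ptr + k]
        ptr += k
        return idx

    roles[take(round(config.fraction_conserved_ge_divergent_as * n))] = "conserved_ge"
    for pattern, frac in config.fraction_polyploid_altered.items():
        idx = take(round(frac * n))
        roles[idx] = "altered"
        patterns[idx] = pattern
    roles[take(round(config.fraction_ploidy_specific * n))] = "ploidy_specific"
    half_stage = round(config.fraction_stage_specific * n / 2)
    roles[take(half_stage)] = "e01_specific"
    roles[take(half_stage)] = "e07_specific"
    roles[take(round(config.fraction_endosperm_specific * n))] = "endosperm_specific"
    roles[take(round(config.fraction_cultivar_divergent * n))] = "cultivar_divergent"
    return roles, patterns


def _stage_spread(cls: str, rng: np.random.Generator) -> np.ndarray:
    """Per-stage within-triad spread, wider for E01-E03 than E04-E07."""
    s = np.empty(10)
    if cls == "balanced":
        bands = {(_WIDE): (5, 14), (_NARROW): (0, 6), (_MID): (3, 10)}
    elif cls == "unbalanced":
        bands = {(_WIDE): (26, 72), (_NARROW): (26, 45), (_MID): (26, 55)}
    else:  # switched: same band everywhere; extremes leave no scaling room
        bands = {(_WIDE): (84, 86.5), (_NARROW): (84, 86.5), (_MID): (84, 86.5)}
    for stages, (lo, hi) in bands.items():
        for t in stages:
            s[t] = rng.uniform(lo, hi)
    return s


def _class_surface(cls: str, rng: np.random.Generator) -> np.ndarray:
    """(3 roles x 10 stages) PSI surface for one triad; rows are lo/mid/hi."""
    s = _stage_spread(cls, rng)
    if cls == "switched":
        lo0 = rng.uniform(6, 8)
        u = rng.uniform(0.2, 0.8)
        lo = np.full(10, lo0)
        hi = lo + s
        mid = lo + u * s
    else:
        c = rng.uniform(22, 78) if cls == "balanced" else rng.uniform(42, 58)
        u = rng.uniform(0.15, 0.85)
        lo = c - s / 2
        hi = c + s / 2
        mid = lo + u * s
    return np.vstack([lo, mid, hi])


def _make_shift_chain(
    s_name: str, s_size: int, t_name: str, t_size: int,
    breakpoints: np.ndarray, deltas: np.ndarray, chain_id: int,
) -> Chain:
    """Colinear chain whose source->target offset changes by ``deltas`` at
    the given source breakpoints (positive: target insertion; negative:
    source insertion)."""
    sizes, dts, dqs = [], [], []
    prev = 0
    for bp, d in zip(breakpoints, deltas):
        d = int(d)
        sizes.append(int(bp) - prev)
        dts.append(max(0, -d))
        dqs.append(max(0, d))
        prev = int(bp) + max(0, -d)
    sizes.append(s_size - prev)
    t_end = sum(sizes) + sum(dqs)
    if t_end != t_size:
        raise AssertionError("inconsistent chain geometry")
    return Chain(
        score=1000, s_name=s_name, s_size=s_size, s_strand="+",
        s_start=0, s_end=s_size, t_name=t_name, t_size=t_size, t_strand="+",
        t_start=0, t_end=t_end, chain_id=chain_id,
        sizes=sizes, dt=dts, dq=dqs,
    )


# ---------------------------------------------------------------------------
# main generator

def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_triads
    samples = make_sample_table(config.replicates)
    variety_names = list(VARIETIES)
    v_index = {v: i for i, v in enumerate(variety_names)}
    subg_index = {s: i for i, s in enumerate(SUBGENOMES)}

    roles, patterns = _assign_roles(config, rng)

    # --- genome geometry and chains -------------------------------------
    a_pos = 1000 + np.arange(n) * GENE_SPACING
    delta_b = rng.choice([0, 50, 120], size=n, p=[0.5, 0.3, 0.2])
    delta_d = rng.choice([0, 50, 120], size=n, p=[0.5, 0.3, 0.2])
    b_pos = a_pos + np.cumsum(delta_b)
    d_pos = a_pos + np.cumsum(delta_d)
    a_size = int(n * GENE_SPACING + 3000)
    b_size = a_size + int(delta_b.sum())
    d_size = a_size + int(delta_d.sum())
    gene_pos = {"A": a_pos, "B": b_pos, "D": d_pos}
    chrom_size = {"A": a_size, "B": b_size, "D": d_size}

    chain_ab = _make_shift_chain("1A", a_size, "1B", b_size, a_pos - 500, delta_b, 1)
    chain_ad = _make_shift_chain("1A", a_size, "1D", d_size, a_pos - 500, delta_d, 2)
    chain_bd = _make_shift_chain("1B", b_size, "1D", d_size, b_pos - 500, delta_d - delta_b, 3)
    chains = {"AB": ChainSet([chain_ab]), "AD": ChainSet([chain_ad]), "BD": ChainSet([chain_bd])}

    # --- planted classes and ancestral PSI surfaces ----------------------
    classes = np.array(["balanced"] * n, dtype=object)
    mixture_idx = rng.choice(3, size=n, p=np.asarray(config.bias_mixture))
    surf = np.zeros((n, 3, 10))  # ancestral PSI per (triad, subgenome, stage)
    role_perm = np.zeros((n, 3), dtype=int)  # which subgenome plays lo/mid/hi
    stage_perm = rng.permutation(10)  # shared shuffle for conserved-GE D member
    for i in range(n):
        role = roles[i]
        if role == "conserved_ge":
            classes[i] = "conserved_ge"
            base = np.linspace(30, 70, 10)
            surf[i, 0] = base
            surf[i, 1] = base[::-1]
            surf[i, 2] = base[stage_perm]
            role_perm[i] = (0, 1, 2)
            continue
        if role == "altered":
            classes[i] = "unbalanced"
            c = rng.uniform(40, 55)
            s = rng.uniform(55, 65)
            u = rng.uniform(0.25, 0.75)
            lo, hi, mid = c - s / 2, c + s / 2, c - s / 2 + u * s
            # A and B take the extremes so the DV-SP contrast qualifies the
            # diad as a tetraploid polyploidization candidate as well
            flip = rng.random() < 0.5
            triple = (np.full(10, hi), np.full(10, mid), np.full(10, lo)) if flip else (
                np.full(10, lo), np.full(10, mid), np.full(10, hi))
            surf[i, 0], surf[i, 2], surf[i, 1] = triple[0], triple[1], triple[2]
            role_perm[i] = (0, 2, 1)
            continue
        if role in ("ploidy_specific", "e01_specific", "e07_specific",
                    "endosperm_specific", "cultivar_divergent"):
            classes[i] = "balanced"
            c = rng.uniform(16, 28)
            s = _stage_spread("balanced", rng)
            u = rng.uniform(0.15, 0.85)
            vals = np.vstack([c - s / 2, c - s / 2 + u * s, c + s / 2])
        else:
            classes[i] = ("balanced", "unbalanced", "switched")[mixture_idx[i]]
            vals = _class_surface(classes[i], rng)
        perm = rng.permutation(3)
        role_perm[i] = perm
        for j, s_idx in enumerate(perm):
            surf[i, s_idx] = vals[j]

    # --- variety-resolved noiseless PSI ----------------------------------
    alt_dir = np.where(surf.mean(axis=2) < 50, 40.0, -40.0)  # (n, 3)
    alt_mask = np.zeros((n, 3), dtype=bool)
    for i in range(n):
        for s in patterns[i]:
            alt_mask[i, subg_index[s]] = True
    alt_shift = alt_dir * alt_mask
    alt_shift_tet = alt_shift.copy()
    alt_shift_tet[:, 2] = 0.0  # tetraploids carry no D subgenome

    cultivar_target = np.array([""] * n, dtype=object)
    cult_idx = np.flatnonzero(roles == "cultivar_divergent")
    for j, i in enumerate(cult_idx):
        cultivar_target[i] = "CS" if j % 2 == 0 else "ST"

    group_shift = 45.0
    psi_vs = np.full((n, 3, len(variety_names), 10), np.nan)
    for v, (vi, (_, ploidy, subg)) in zip(variety_names, enumerate(VARIETIES.values())):
        for s in subg:
            si = subg_index[s]
            val = surf[:, si, :].copy()
            if ploidy == "hexaploid":
                val += alt_shift[:, si][:, None]
                val[roles == "ploidy_specific"] += group_shift
                shift_cult = (cultivar_target == v) & (s == "A")
                val[shift_cult] += 40.0
            elif ploidy == "tetraploid":
                val += alt_shift_tet[:, si][:, None]
                shift_cult = (cultivar_target == v) & (s == "A")
                val[shift_cult] += 40.0
            val[roles == "e01_specific", 0] += group_shift
            val[roles == "e07_specific", 6] += group_shift
            val[np.ix_(roles == "endosperm_specific", [7, 8])] += group_shift
            psi_vs[:, si, vi, :] = np.clip(val, 1.0, 99.0)

    # --- phylostrata and isoform counts ----------------------------------
    ps_levels = rng.integers(1, 15, size=n)
    w = np.asarray(config.isoform_count_weights, dtype=float)
    w = w / w.sum()
    w_young = w * config.ps_young_isoform_boost ** np.arange(len(w))
    w_young = w_young / w_young.sum()
    n_iso = np.empty((n, 3), dtype=int)
    for i in range(n):
        weights = w_young if ps_levels[i] >= 13 else w
        n_iso[i] = rng.choice(np.arange(2, 2 + len(w)), size=3, p=weights)

    # --- gene models, transcripts and events ------------------------------
    etype_probs = np.asarray(config.event_type_mixture, dtype=float)
    etype_probs = etype_probs / etype_probs.sum()
    etype_order = ("A3", "A5", "RI", "SE", "AF", "AL", "MX")
    primary_type = rng.choice(etype_order, size=n, p=etype_probs)

    tx_rows, ev_rows = [], []
    tx_triad, tx_subg, tx_iso, tx_niso = [], [], [], []
    ev_triad, ev_subg, ev_kind = [], [], []
    for i in range(n):
        for s in SUBGENOMES:
            si = subg_index[s]
            g = int(gene_pos[s][i])
            gid = f"G{i:04d}{s}"
            chrom = CHROMS[s]
            k = int(n_iso[i, si])
            tids = [f"{gid}.t{j + 1}" for j in range(k)]
            for j, tid in enumerate(tids):
                tx_rows.append(
                    {"transcript_id": tid, "gene_id": gid, "subgenome": s,
                     "chrom": chrom, "start": g, "end": g + GENE_LENGTH, "strand": "+"}
                )
                tx_triad.append(i)
                tx_subg.append(si)
                tx_iso.append(j)
                tx_niso.append(k)
            start = g + PRIMARY_OFFSET
            ev_rows.append(
                {"event_id": make_event_id(gid, primary_type[i], chrom, start,
                                           start + EVENT_LENGTH, "+"),
                 "gene_id": gid, "subgenome": s, "event_type": primary_type[i],
                 "chrom": chrom, "start": start, "end": start + EVENT_LENGTH,
                 "strand": "+", "inclusion": (tids[0],), "total": (tids[0], tids[1])}
            )
            ev_triad.append(i)
            ev_subg.append(si)
            ev_kind.append("primary")
            for x in range(max(0, k - 3)):
                estart = g + EXTRA_OFFSET[s] + x * EXTRA_SPACING
                et = str(rng.choice(etype_order, p=etype_probs))
                ev_rows.append(
                    {"event_id": make_event_id(gid, et, chrom, estart,
                                               estart + EVENT_LENGTH, "+"),
                     "gene_id": gid, "subgenome": s, "event_type": et,
                     "chrom": chrom, "start": estart, "end": estart + EVENT_LENGTH,
                     "strand": "+", "inclusion": (tids[2 + x],),
                     "total": (tids[2 + x], tids[3 + x])}
                )
                ev_triad.append(i)
                ev_subg.append(si)
                ev_kind.append("extra")

    transcripts = pd.DataFrame(tx_rows).set_index("transcript_id")
    catalog = pd.DataFrame(ev_rows).set_index("event_id")
    tx_triad = np.array(tx_triad)
    tx_subg = np.array(tx_subg)
    tx_iso = np.array(tx_iso)
    tx_niso = np.array(tx_niso)
    ev_triad = np.array(ev_triad)
    ev_subg = np.array(ev_subg)
    ev_kind = np.array(ev_kind)

    # --- gene expression trajectories (log scale) -------------------------
    mu, sigma = config.tpm_lognormal_params
    levels = np.zeros((n, 3, 10))
    start_level = rng.normal(mu, sigma, size=(n, 3))
    steps = rng.normal(0, 0.35, size=(n, 3, 9))
    levels[:, :, 0] = start_level
    for t in range(1, 10):
        levels[:, :, t] = levels[:, :, t - 1] + steps[:, :, t - 1]
    conserved = roles == "conserved_ge"
    levels[conserved, 1, :] = levels[conserved, 0, :]
    levels[conserved, 2, :] = levels[conserved, 0, :]
    ge_skew = np.array([""] * n, dtype=object)
    skew_idx = np.flatnonzero(roles == "plain")
    n_skew = round(config.fraction_ge_skewed * n)
    skew_idx = skew_idx[: n_skew]
    floor = np.full((n, 3), np.log(4.0))
    for i in skew_idx:
        s = int(rng.integers(0, 3))
        if rng.random() < 0.5:
            levels[i, s] += 2.5
            ge_skew[i] = f"{SUBGENOMES[s]}_dominant"
        else:
            levels[i, s] -= 2.5
            ge_skew[i] = f"{SUBGENOMES[s]}_suppressed"
            floor[i, s] = np.log(2.5)
    levels = np.clip(levels, floor[:, :, None], 7.0)

    # --- emit per-sample transcript TPMs ----------------------------------
    stage_of = {s: t for t, s in enumerate(STAGES)}
    T = len(transcripts)
    tpm = np.zeros((T, len(samples)))
    present_mask = {
        v: np.isin(np.array(SUBGENOMES), list(VARIETIES[v][2])) for v in variety_names
    }
    frac_sigma = config.noise_sd_psi / 25.0
    is_primary_tx = tx_iso < 2
    for col, (sid, srow) in enumerate(samples.iterrows()):
        v = srow["variety"]
        vi = v_index[v]
        t = stage_of[srow["stage_tissue"]]
        g_tpm = np.exp(levels[:, :, t])
        if config.tpm_replicate_sigma > 0:
            g_tpm = g_tpm * np.exp(rng.normal(0, config.tpm_replicate_sigma, size=(n, 3)))
        p = psi_vs[:, :, vi, t]
        if config.noise_sd_psi > 0:
            p = np.clip(p + rng.normal(0, config.noise_sd_psi, size=(n, 3)), 0.0, 100.0)
        jitter = (
            np.exp(rng.normal(0, frac_sigma, size=T)) if frac_sigma > 0 else np.ones(T)
        )
        base = g_tpm[tx_triad, tx_subg]
        p_tx = p[tx_triad, tx_subg]
        # the primary event takes half the gene mass (all of it for 2-isoform
        # genes) so that gene TPM sums exactly to the planted trajectory
        ev_frac = np.where(tx_niso == 2, 1.0, 0.5)
        vals = np.zeros(T)
        vals[tx_iso == 0] = (ev_frac * base * p_tx / 100.0)[tx_iso == 0]
        vals[tx_iso == 1] = (ev_frac * base * (1.0 - p_tx / 100.0))[tx_iso == 1]
        rem = ~is_primary_tx
        wsum = np.zeros((n, 3))
        np.add.at(wsum, (tx_triad[rem], tx_subg[rem]), jitter[rem])
        share = jitter[rem] / wsum[tx_triad[rem], tx_subg[rem]]
        vals[rem] = 0.5 * base[rem] * share
        absent = ~present_mask[v][tx_subg]
        vals[absent] = 0.0
        tpm[:, col] = vals

    quant = TranscriptQuant(
        tpm=pd.DataFrame(tpm, index=transcripts.index, columns=samples.index),
        transcripts=transcripts,
    )

    # --- truth tables ------------------------------------------------------
    sample_vi = np.array([v_index[v] for v in samples["variety"]])
    sample_t = np.array([stage_of[s] for s in samples["stage_tissue"]])
    truth_psi = psi_vs[ev_triad[:, None], ev_subg[:, None], sample_vi[None, :], sample_t[None, :]]
    truth_psi[ev_kind == "extra"] = np.where(
        np.isnan(truth_psi[ev_kind == "extra"]), np.nan, 50.0
    )
    psi_true = pd.DataFrame(truth_psi, index=catalog.index, columns=samples.index)

    prim = ev_kind == "primary"
    prim_events = catalog.index.to_numpy()[prim]
    triad_rows = []
    for i in range(n):
        members = {
            s: prim_events[(ev_triad[prim] == i) & (ev_subg[prim] == subg_index[s])][0]
            for s in SUBGENOMES
        }
        triad_rows.append(
            {
                "triad_id": f"t{i:04d}",
                "event_A": members["A"], "event_B": members["B"], "event_D": members["D"],
                "gene_A": f"G{i:04d}A", "gene_B": f"G{i:04d}B", "gene_D": f"G{i:04d}D",
                "event_type": primary_type[i],
                "planted_class": classes[i],
                "role": roles[i],
                "altered_pattern": patterns[i],
                "altered_pattern_tetraploid": "".join(
                    s for s in patterns[i] if s in "AB"
                ),
                "cultivar_target": cultivar_target[i],
                "ge_skew": ge_skew[i],
                "ps_level": int(ps_levels[i]),
            }
        )
    triads_truth = pd.DataFrame(triad_rows).set_index("triad_id")

    # diploid-divergence candidacy from the noiseless diploid surfaces
    dv = psi_vs[:, 0, v_index["DV"], :]
    sp = psi_vs[:, 1, v_index["SP"], :]
    ta = psi_vs[:, 2, v_index["TA"], :]
    pair_max_hex = np.nanmax(
        np.maximum.reduce([np.abs(dv - sp), np.abs(dv - ta), np.abs(sp - ta)]), axis=1
    )
    triads_truth["diploid_candidate_hexaploid"] = pair_max_hex >= 50.0
    triads_truth["diploid_candidate_tetraploid"] = np.nanmax(np.abs(dv - sp), axis=1) >= 50.0

    bias_rows = []
    for v in ("AC", "CS"):
        vi = v_index[v]
        vals = psi_vs[:, :, vi, :]  # (n, 3, 10)
        rng_ = vals.max(axis=1) - vals.min(axis=1)
        for t, stage in enumerate(STAGES):
            cat = np.where(
                rng_[:, t] < 20.0, "balanced",
                np.where(rng_[:, t] < 80.0, "unbalanced", "switched"),
            )
            bias_rows.extend(
                {"triad_id": f"t{i:04d}", "variety": v, "stage_tissue": stage,
                 "category": cat[i]}
                for i in range(n)
            )
    bias_true = pd.DataFrame(bias_rows)

    dom_rows = []
    g = np.exp(levels)  # (n, 3, 10)
    for t, stage in enumerate(STAGES):
        groups = assign_dominance(g[:, :, t])
        dom_rows.extend(
            {"triad_id": f"t{i:04d}", "stage_tissue": stage, "dominance": groups[i]}
            for i in range(n)
        )
    dominance_true = pd.DataFrame(dom_rows)

    truth = PlantedTruth(
        triads=triads_truth, psi_true=psi_true,
        bias_true=bias_true, dominance_true=dominance_true,
    )
    ps = pd.Series(
        {f"G{i:04d}{s}": int(ps_levels[i]) for i in range(n) for s in SUBGENOMES},
        name="ps_level",
    )
    ps.index.name = "gene_id"
    return SimulatedDataset(
        quant=quant, samples=samples, catalog=catalog, chains=chains,
        ps=ps, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# fixture emission

def emit_fixture(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write the complete synthetic dataset to disk; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)
    files = {
        "samples": "samples.tsv",
        "quant": "quant.tsv",
        "events": "events.ioe",
        "chain_AB": "chain_AB.chain",
        "chain_AD": "chain_AD.chain",
        "chain_BD": "chain_BD.chain",
        "ps": "ps_levels.tsv",
        "gene_models": "gene_models.gtf",
        "truth_triads": "truth_triads.tsv",
        "truth_psi": "truth_psi.tsv",
        "truth_bias": "truth_bias.tsv",
        "truth_dominance": "truth_dominance.tsv",
    }
    write_samples(data.samples, out / files["samples"])
    write_quant_table(data.quant, out / files["quant"])
    write_ioe(data.catalog, out / files["events"])
    for key in ("AB", "AD", "BD"):
        write_chain(data.chains[key].chains, out / files[f"chain_{key}"])
    write_ps_table(data.ps, out / files["ps"])
    write_gtf(data.quant.transcripts, out / files["gene_models"])
    data.truth.triads.to_csv(out / files["truth_triads"], sep="\t")
    data.truth.psi_true.to_csv(out / files["truth_psi"], sep="\t", na_rep="NA",
                               float_format="%.6f")
    data.truth.bias_true.to_csv(out / files["truth_bias"], sep="\t", index=False)
    data.truth.dominance_true.to_csv(out / files["truth_dominance"], sep="\t", index=False)
    manifest = {"seed": config.rng_seed, "n_triads": config.n_triads, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
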