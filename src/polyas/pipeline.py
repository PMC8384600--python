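"""End-to-end orchestration: simulate -> PSI -> triads -> bias -> specificity
-> trees -> polyploidization -> phylostrata, with all stage outputs on disk.

Re-running with an identical config and seed reproduces identical outputs
byte for byte (no timestamps are written; every stochastic step derives its
seed from the configured one).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chain import ChainSet, read_chain
from .config import AnalysisConfig, SimulationConfig, save_config
from .io import (
    STAGES,
    read_ioe,
    read_ps_table,
    read_quant_table,
    read_samples,
    write_psi_matrix,
)
from .simulate import emit_fixture
from . import evolution, psi as psi_mod, specificity, trees as trees_mod, triads as triads_mod


@dataclass
class DataBundle:
    quant: object
    samples: pd.DataFrame
    catalog: pd.DataFrame
    chains: dict[str, ChainSet]
    ps: pd.Series


def load_data(data_dir: str | Path) -> DataBundle:
    """Load a dataset directory laid out by :func:`polyas.simulate.emit_fixture`."""
    d = Path(data_dir)
    samples = read_samples(d / "samples.tsv")
    return DataBundle(
        quant=read_quant_table(d / "quant.tsv", samples),
        samples=samples,
        catalog=read_ioe(d / "events.ioe"),
        chains={k: ChainSet(read_chain(d / f"chain_{k}.chain")) for k in ("AB", "AD", "BD")},
        ps=read_ps_table(d / "ps_levels.tsv"),
    )


def config_hash(analysis: AnalysisConfig, simulation: SimulationConfig) -> str:
    payload = json.dumps(
        {"analysis": dataclasses.asdict(analysis), "simulation": dataclasses.asdict(simulation)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f", **kw)


def run_all(
    analysis: AnalysisConfig,
    simulation: SimulationConfig,
    out_dir: str | Path,
) -> dict:
    """Run the full pipeline on a freshly simulated dataset.

    Returns the run manifest; every stage's tables land under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": simulation.rng_seed,
        "config_hash": config_hash(analysis, simulation),
        "stages": {},
    }
    summary: dict = {}

    # -- simulate ----------------------------------------------------------
    fixture_dir = out / "fixture"
    emit_fixture(simulation, fixture_dir)
    data = load_data(fixture_dir)
    manifest["stages"]["simulate"] = "ok"
    summary["n_samples"] = int(len(data.samples))
    summary["n_transcripts"] = int(len(data.quant.tpm))
    summary["n_events"] = int(len(data.catalog))

    # -- PSI + event classes ----------------------------------------------
    psi_res = psi_mod.compute_psi(data.quant, data.catalog, analysis)
    write_psi_matrix(psi_res.psi, out / "psi.tsv")
    reliable = psi_mod.filter_reliable_events(psi_res, data.samples, analysis)
    psi_rel = psi_res.psi.loc[reliable]
    labels = psi_mod.classify_pan_variant(psi_rel, analysis)
    _write(labels, out / "event_labels.tsv", index_label="event_id")
    profile = psi_mod.event_type_profile(data.catalog.loc[reliable], "subgenome")
    _write(profile, out / "event_type_profile.tsv", index_label="group")
    genes = psi_mod.aggregate_gene_tpm(data.quant, data.samples, analysis)
    manifest["stages"]["psi"] = "ok"
    summary["n_reliable_events"] = int(len(reliable))
    summary["n_pan_as"] = int(labels["pan"].sum())
    summary["n_variant_as"] = int(labels["variant"].sum())

    # -- triads and splicing bias ------------------------------------------
    cat_rel = data.catalog.loc[reliable]
    catalogs = {s: cat_rel[cat_rel["subgenome"] == s] for s in "ABD"}
    triads = triads_mod.build_triads(catalogs, data.chains, analysis)
    _write(triads, out / "triads.tsv", index_label="triad_id")
    stage_means = psi_mod.stage_mean_psi(psi_rel, data.samples)
    bias = triads_mod.triad_psi_table(triads, stage_means, ("AC", "CS"), analysis)
    _write(bias, out / "triad_bias.tsv", index=False)
    gene_means = psi_mod.stage_mean_psi(genes.drop(columns="expressed"), data.samples)
    dom = triads_mod.ge_dominance_table(triads, gene_means, ("AC", "CS"))
    bgba, bgba_consistent = triads_mod.balanced_ge_biased_as(bias, dom)
    _write(bgba, out / "balanced_ge_biased_as.tsv", index=False)
    manifest["stages"]["triads"] = "ok"
    summary["n_triads"] = int(len(triads))
    e01 = bias[(bias["variety"] == "AC") & (bias["stage_tissue"] == "E01")]
    for cat in triads_mod.BIAS_CATEGORIES:
        summary[f"bias_{cat}_E01_AC"] = int((e01["category"] == cat).sum())
    summary["n_balanced_ge_biased_as_rows"] = int(len(bgba))
    summary["n_biased_as_consistent_embryo"] = int(len(bgba_consistent))

    # -- specificity --------------------------------------------------------
    specific_frames = []
    for s in "ABD":
        sub = psi_rel.loc[psi_rel.index.isin(catalogs[s].index)]
        carriers = data.samples.index[
            data.samples["subgenomes_present"].str.contains(s)
        ]
        clusters = specificity.cluster_events(
            sub[carriers], k=analysis.kmeans_k, seed=analysis.rng_seed, config=analysis
        )
        for grouping in ("ploidy", "stage_tissue", "tissue_class"):
            _, events_tab = specificity.call_specific_clusters(
                clusters, data.samples, grouping, analysis
            )
            events_tab.insert(0, "subgenome", s)
            events_tab.insert(1, "grouping", grouping)
            specific_frames.append(events_tab)
    specific_frames = [f for f in specific_frames if not f.empty]
    specific = (
        pd.concat(specific_frames, ignore_index=True)
        if specific_frames
        else pd.DataFrame(columns=["subgenome", "grouping", "event_id", "cluster",
                                   "group", "direction", "centroid_r"])
    )
    _write(specific, out / "specific_events.tsv", index=False)
    manifest["stages"]["specific"] = "ok"
    summary["n_specific_calls"] = int(len(specific))

    # -- divergence trees ----------------------------------------------------
    corr = trees_mod.triad_correlations(triads, gene_means, stage_means, "AC",
                                        config=analysis)
    _write(corr, out / "triad_correlations.tsv", index_label="triad_id")
    cgda = trees_mod.conserved_ge_divergent_as(corr)
    summary["n_conserved_ge_divergent_as"] = int(len(cgda))
    leaves = [(v, s) for v in ("AC", "CS") for s in "ABD"]
    boot_rows = []
    newicks = []
    for t, stage in enumerate(STAGES):
        leaf_m = trees_mod.leaf_psi_matrix(stage_means, triads, leaves, stage)
        dm = trees_mod.subgenome_distance_matrix(leaf_m)
        if dm is None:
            continue
        tree = trees_mod.neighbor_joining(dm)
        newicks.append((stage, str(tree)))
        lengths = trees_mod.bootstrap_tree_lengths(
            leaf_m, analysis, rng=analysis.rng_seed * 1000 + t
        )
        boot_rows.append(pd.DataFrame({"stage_tissue": stage, "length": lengths}))
    boot = pd.concat(boot_rows, ignore_index=True)
    _write(boot, out / "bootstrap_tree_lengths.tsv", index=False)
    with open(out / "trees.nwk", "w") as fh:
        for stage, nwk in newicks:
            fh.write(f"{stage}\t{nwk}")
    groups = {
        stage: grp["length"].dropna().to_numpy()
        for stage, grp in boot.groupby("stage_tissue")
    }
    letters = trees_mod.duncan_mrt(groups, analysis.alpha)
    _write(letters, out / "tree_length_duncan.tsv")
    manifest["stages"]["trees"] = "ok"
    early = boot[boot["stage_tissue"].isin(["E01", "E02", "E03"])]["length"]
    late = boot[boot["stage_tissue"].isin(["E04", "E05", "E06", "E07"])]["length"]
    summary["mean_tree_length_E01_E03"] = float(np.round(early.mean(), 6))
    summary["mean_tree_length_E04_E07"] = float(np.round(late.mean(), 6))

    # -- polyploidization ----------------------------------------------------
    diads = triads_mod.build_triads({s: catalogs[s] for s in "AB"}, data.chains, analysis)
    stage_means_all = stage_means  # includes diploid varieties
    cand_hex = evolution.diploid_divergent_candidates(
        triads, stage_means_all, analysis, "hexaploid"
    )
    cand_tet = evolution.diploid_divergent_candidates(
        diads, stage_means_all, analysis, "tetraploid"
    )
    calls_hex = evolution.polyploidization_altered(cand_hex, stage_means_all, analysis, "hexaploid")
    calls_tet = evolution.polyploidization_altered(cand_tet, stage_means_all, analysis, "tetraploid")
    _write(calls_hex, out / "polyploid_altered_hexaploid.tsv", index_label="triad_id")
    _write(calls_tet, out / "polyploid_altered_tetraploid.tsv", index_label="triad_id")
    shared = evolution.shared_altered_across_ploidies(calls_tet, calls_hex, diads, triads)
    _write(shared, out / "polyploid_altered_shared.tsv")
    manifest["stages"]["polyploid"] = "ok"
    summary["n_candidates_hexaploid"] = int(len(cand_hex))
    summary["n_candidates_tetraploid"] = int(len(cand_tet))
    summary["n_altered_hexaploid"] = int((calls_hex["altered_pattern"] != "none").sum())
    summary["n_altered_tetraploid"] = int((calls_tet["altered_pattern"] != "none").sum())
    summary["n_shared_altered"] = int(len(shared))

    # -- phylostrata ---------------------------------------------------------
    dist, counts, n_missing = evolution.ps_event_distribution(data.catalog, reliable, data.ps)
    _write(dist, out / "ps_event_distribution.tsv", index_label="ps_level")
    young_mean, old_mean, p_trend = evolution.ps_young_old_trend(counts, data.ps)
    manifest["stages"]["phylostrata"] = "ok"
    summary["ps_mean_events_young"] = float(np.round(young_mean, 6))
    summary["ps_mean_events_old"] = float(np.round(old_mean, 6))
    summary["ps_trend_p"] = float(np.format_float_scientific(p_trend, 6))
    summary["ps_genes_missing_level"] = int(n_missing)

    save_config(analysis, simulation, out / "config.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
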