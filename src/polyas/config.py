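"""Analysis and simulation configuration.

All thresholds live on the scales they are quoted on in the wheat AS
literature: PSI in 0..100 points, correlations in -1..1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for the downstream AS analyses.

    Attributes
    ----------
    min_event_tpm:
        Minimum summed TPM over an event's total transcripts for the PSI of
        that event to be considered measurable in a sample; below it PSI is NA.
    psi_reliable_low, psi_reliable_high:
        Open reliability window; an event is kept when some stage/tissue
        replicate-mean PSI falls strictly inside (low, high).
    pan_fraction:
        An event is PanAS when the fraction of its non-NA samples with PSI
        strictly inside the reliability window strictly exceeds this value.
    min_defined_samples:
        Minimum number of non-NA samples required before an event may be
        called PanAS ("samples with sufficient read coverage" proxy).
    variant_delta:
        An event is VariantAS when max-min PSI over non-NA samples exceeds
        this many PSI points.  The same delta defines cultivar-divergent
        events.
    balanced_max, switched_min:
        Triad-bias category boundaries on the within-triad PSI range:
        [0, balanced_max) balanced, [balanced_max, switched_min) unbalanced,
        [switched_min, 100] switched.
    ge_conservation_r:
        All three pairwise Pearson r on gene TPM must exceed this for a triad
        to count as GE-conserved.
    as_divergence_rho:
        At least one pairwise Spearman rho on PSI below this flags a triad as
        AS-divergent.
    n_bootstrap:
        Bootstrap replicates for total tree length distributions.
    diploid_delta:
        Minimum pairwise diploid PSI difference (in >=1 stage) for a triad to
        be a polyploidization candidate.
    polyploid_shift:
        Minimum |polyploid - diploid ancestor| PSI shift for a subgenome to be
        called altered by polyploidization (alpha-gated).
    alpha:
        Significance level for Welch tests and Duncan's MRT.
    kmeans_k:
        Integer cluster count or "auto" (silhouette over 2..kmeans_max_k).
    specificity_r_min:
        Minimum |Pearson r| between a cluster centroid and a group indicator
        for a group-specific call.
    min_overlap_fraction:
        Minimum fraction of an interval that must map through a chain (and
        minimum reciprocal overlap fraction) during 1:1 event matching.
    require_all_chains:
        When True, triads whose B->D consistency check fails are dropped
        instead of only being flagged.
    """

    min_event_tpm: float = 1.0
    psi_reliable_low: float = 5.0
    psi_reliable_high: float = 95.0
    pan_fraction: float = 0.80
    min_defined_samples: int = 10
    variant_delta: float = 25.0
    balanced_max: float = 20.0
    switched_min: float = 80.0
    ge_conservation_r: float = 0.8
    as_divergence_rho: float = 0.5
    n_bootstrap: int = 100
    diploid_delta: float = 50.0
    polyploid_shift: float = 20.0
    alpha: float = 0.05
    kmeans_k: int | str = "auto"
    kmeans_max_k: int = 24
    specificity_r_min: float = 0.7
    min_overlap_fraction: float = 0.5
    require_all_chains: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.psi_reliable_low < self.psi_reliable_high < 100:
            raise ValueError("reliability window must satisfy 0 < low < high < 100")
        if not 0 <= self.balanced_max <= self.switched_min <= 100:
            raise ValueError("bias ranges must satisfy 0 <= balanced_max <= switched_min <= 100")
        if not 0 < self.pan_fraction < 1:
            raise ValueError("pan_fraction must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Design of the synthetic grain-development dataset.

    The emitted design mirrors the sampling layout of the wheat embryogenesis
    study it emulates: 7 varieties (2 hexaploid AABBDD, 2 tetraploid AABB and
    the three diploid ancestors AA/BB/DD), 10 stage/tissue classes E01-E10 and
    2 replicates, i.e. 140 libraries; homoeologous triad gene models with
    multiple isoforms per locus and the seven AS event types.
    """

    n_triads: int = 300
    replicates: int = 2
    # distribution over isoforms-per-gene 2..8; old genes
    isoform_count_weights: tuple[float, ...] = (0.46, 0.20, 0.12, 0.08, 0.06, 0.05, 0.03)
    # event type mixture over (A3, A5, RI, SE, AF, AL, MX)
    event_type_mixture: tuple[float, ...] = (0.33, 0.19, 0.16, 0.13, 0.13, 0.05, 0.006)
    bias_mixture: tuple[float, float, float] = (0.60, 0.30, 0.10)  # balanced, unbalanced, switched
    fraction_ploidy_specific: float = 0.05
    fraction_stage_specific: float = 0.05  # split evenly between E01 and E07
    fraction_endosperm_specific: float = 0.05
    fraction_conserved_ge_divergent_as: float = 0.10
    fraction_cultivar_divergent: float = 0.02
    fraction_ge_skewed: float = 0.15
    fraction_polyploid_altered: dict[str, float] = field(
        default_factory=lambda: {
            "A": 0.02, "B": 0.02, "D": 0.02,
            "AB": 0.01, "AD": 0.01, "BD": 0.01, "ABD": 0.01,
        }
    )
    noise_sd_psi: float = 5.0
    tpm_lognormal_params: tuple[float, float] = (3.0, 0.8)
    tpm_replicate_sigma: float = 0.15
    ps_young_isoform_boost: float = 1.6
    allow_inversions: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.bias_mixture) - 1.0) > 1e-9:
            raise ValueError("bias_mixture must sum to 1")
        if any(not 0 <= p <= 1 for p in self.bias_mixture):
            raise ValueError("bias_mixture proportions must be in [0, 1]")
        special = (
            self.fraction_ploidy_specific
            + self.fraction_stage_specific
            + self.fraction_endosperm_specific
            + self.fraction_conserved_ge_divergent_as
            + self.fraction_cultivar_divergent
            + sum(self.fraction_polyploid_altered.values())
        )
        if special > 0.9:
            raise ValueError("special-role fractions leave no plain triads")
        if self.noise_sd_psi < 0:
            raise ValueError("noise_sd_psi must be >= 0")


def _to_dict(cfg: Any) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_config(analysis: AnalysisConfig, simulation: SimulationConfig, path: str | Path) -> None:
    payload = {"analysis": _to_dict(analysis), "simulation": _to_dict(simulation)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _from_dict(cls, d: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} key: {k}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[AnalysisConfig, SimulationConfig]:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    analysis = _from_dict(AnalysisConfig, payload.get("analysis", {}))
    simulation = _from_dict(SimulationConfig, payload.get("simulation", {}))
    return analysis, simulation
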