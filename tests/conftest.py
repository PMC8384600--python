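"""Shared fixtures: simulated datasets at zero and moderate PSI noise.

Session-scoped so the 300-triad datasets are generated once; all fixture
data is produced programmatically at test time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polyas.config import AnalysisConfig, SimulationConfig
from polyas import psi as psi_mod
from polyas.simulate import simulate_dataset


@pytest.fixture(scope="session")
def analysis() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def ds0():
    """Zero-noise dataset: PSI of emitted TPMs equals the planted surface."""
    return simulate_dataset(
        SimulationConfig(n_triads=300, noise_sd_psi=0.0, tpm_replicate_sigma=0.0, rng_seed=11)
    )


@pytest.fixture(scope="session")
def ds5():
    """Dataset at the study's working noise level (5 PSI points)."""
    return simulate_dataset(SimulationConfig(n_triads=300, noise_sd_psi=5.0, rng_seed=11))


def _derived(ds, analysis):
    res = psi_mod.compute_psi(ds.quant, ds.catalog, analysis)
    reliable = psi_mod.filter_reliable_events(res, ds.samples, analysis)
    stage_means = psi_mod.stage_mean_psi(res.psi.loc[reliable], ds.samples)
    genes = psi_mod.aggregate_gene_tpm(ds.quant, ds.samples, analysis)
    gene_means = psi_mod.stage_mean_psi(genes.drop(columns="expressed"), ds.samples)
    return {
        "psi": res, "reliable": reliable,
        "stage_means": stage_means, "gene_means": gene_means,
    }


@pytest.fixture(scope="session")
def derived0(ds0, analysis):
    return _derived(ds0, analysis)


@pytest.fixture(scope="session")
def derived5(ds5, analysis):
    return _derived(ds5, analysis)


def make_random_quant_catalog(rng: np.random.Generator, n_events: int, n_samples: int):
    """Random transcript table + binary event catalog for oracle checks."""
    from polyas.io import TranscriptQuant, make_event_id

    tx_rows, ev_rows, tpm = [], [], []
    for i in range(n_events):
        gid = f"R{i:04d}A"
        k = int(rng.integers(2, 5))
        tids = [f"{gid}.t{j}" for j in range(k)]
        for tid in tids:
            tx_rows.append(
                {"transcript_id": tid, "gene_id": gid, "subgenome": "A",
                 "chrom": "1A", "start": 100 * i, "end": 100 * i + 50, "strand": "+"}
            )
            tpm.append(rng.uniform(0, 10, size=n_samples))
        n_inc = int(rng.integers(1, k))
        ev_rows.append(
            {"event_id": make_event_id(gid, "SE", "1A", 100 * i, 100 * i + 40, "+"),
             "gene_id": gid, "subgenome": "A", "event_type": "SE",
             "chrom": "1A", "start": 100 * i, "end": 100 * i + 40, "strand": "+",
             "inclusion": tuple(tids[:n_inc]), "total": tuple(tids)}
        )
    transcripts = pd.DataFrame(tx_rows).set_index("transcript_id")
    cols = [f"s{j}" for j in range(n_samples)]
    quant = TranscriptQuant(
        tpm=pd.DataFrame(np.array(tpm), index=transcripts.index, columns=cols),
        transcripts=transcripts,
    )
    catalog = pd.DataFrame(ev_rows).set_index("event_id")
    return quant, catalog
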