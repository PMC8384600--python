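"""PSI quantification, reliability filtering and PanAS/VariantAS labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyas.config import AnalysisConfig
from polyas.io import TranscriptQuant, make_event_id, make_sample_table
from polyas.psi import (
    aggregate_gene_tpm,
    classify_pan_variant,
    compute_psi,
    event_type_profile,
    filter_reliable_events,
    stage_mean_psi,
)

from conftest import make_random_quant_catalog


def _quant_from(tpm_by_tx: dict[str, list[float]], gene="g1"):
    cols = [f"s{i}" for i in range(len(next(iter(tpm_by_tx.values()))))]
    transcripts = pd.DataFrame(
        {"gene_id": gene, "subgenome": "A", "chrom": "1A", "start": 0, "end": 10,
         "strand": "+"},
        index=pd.Index(list(tpm_by_tx), name="transcript_id"),
    )
    tpm = pd.DataFrame(list(tpm_by_tx.values()), index=transcripts.index, columns=cols)
    return TranscriptQuant(tpm=tpm, transcripts=transcripts)


def _event(inclusion, total, gene="g1"):
    return pd.DataFrame(
        [{"event_id": make_event_id(gene, "SE", "1A", 0, 10, "+"), "gene_id": gene,
          "subgenome": "A", "event_type": "SE", "chrom": "1A", "start": 0, "end": 10,
          "strand": "+", "inclusion": tuple(inclusion), "total": tuple(total)}]
    ).set_index("event_id")


@pytest.mark.parametrize(
    "tpms,expected",
    [({"t1": [5.0], "t2": [5.0]}, 50.0),       # equal split
     ({"t1": [0.0], "t2": [4.0]}, 0.0),        # zero numerator
     ({"t1": [0.25], "t2": [0.25]}, np.nan)],  # total 0.5 < 1 TPM -> NA
)
def test_compute_psi_basic_cases(tpms, expected):
    res = compute_psi(_quant_from(tpms), _event(["t1"], ["t1", "t2"]))
    value = res.psi.iloc[0, 0]
    if np.isnan(expected):
        assert np.isnan(value)
    else:
        assert value == pytest.approx(expected)


def test_compute_psi_unknown_transcript_names_event():
    quant = _quant_from({"t1": [1.0], "t2": [1.0]})
    cat = _event(["t1"], ["t1", "tX"])
    with pytest.raises(KeyError, match="tX"):
        compute_psi(quant, cat)


def test_compute_psi_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    quant, catalog = make_random_quant_catalog(rng, n_events=50, n_samples=8)
    res = compute_psi(quant, catalog)
    for eid, row in catalog.iterrows():
        inc = sum(quant.tpm.loc[t] for t in row["inclusion"])
        tot = sum(quant.tpm.loc[t] for t in row["total"])
        for s in quant.tpm.columns:
            got = res.psi.loc[eid, s]
            if tot[s] < 1.0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(100.0 * inc[s] / tot[s], abs=1e-9)


def test_binary_event_psi_complement_sums_to_100():
    rng = np.random.default_rng(6)
    quant = _quant_from({"t1": rng.uniform(1, 5, 6).tolist(),
                         "t2": rng.uniform(1, 5, 6).tolist()})
    fwd = compute_psi(quant, _event(["t1"], ["t1", "t2"]))
    rev = compute_psi(quant, _event(["t2"], ["t1", "t2"]))
    total = fwd.psi.iloc[0] + rev.psi.iloc[0]
    assert np.allclose(total.dropna(), 100.0)


@given(scale=st.floats(min_value=0.5, max_value=50))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_psi_invariant_under_global_rescaling(scale):
    quant = _quant_from({"t1": [2.0, 6.0], "t2": [6.0, 2.0]})
    scaled = TranscriptQuant(tpm=quant.tpm * scale, transcripts=quant.transcripts)
    cat = _event(["t1"], ["t1", "t2"])
    a = compute_psi(quant, cat).psi
    b = compute_psi(scaled, cat).psi
    mask = a.notna() & b.notna()
    assert np.allclose(a.values[mask.values], b.values[mask.values])


# ----------------------------------------------------------------- reliability

def _psi_result_for(values_by_sample: dict[str, float], analysis):
    """One event, values per sample id; totals high enough to be defined."""
    samples = make_sample_table(2)
    psi = pd.DataFrame(np.nan, index=["e1"], columns=samples.index)
    for sid, v in values_by_sample.items():
        psi.loc["e1", sid] = v
    from polyas.psi import PSIResult
    return PSIResult(psi=psi, total_tpm=psi.notna().astype(float) * 10), samples


def test_reliable_filter_keeps_mid_range_and_drops_extremes(analysis):
    res, samples = _psi_result_for({"AC_E01_r1": 50.0, "AC_E01_r2": 50.0}, analysis)
    assert list(filter_reliable_events(res, samples, analysis)) == ["e1"]
    res2, _ = _psi_result_for(
        {"AC_E01_r1": 0.0, "AC_E01_r2": 0.0, "CS_E02_r1": 100.0, "CS_E02_r2": 100.0},
        analysis,
    )
    assert len(filter_reliable_events(res2, samples, analysis)) == 0


def test_reliable_filter_boundary_is_strict(analysis):
    res, samples = _psi_result_for({"AC_E01_r1": 95.0, "AC_E01_r2": 95.0}, analysis)
    assert len(filter_reliable_events(res, samples, analysis)) == 0


def test_reliable_filter_optional_pvalue_gate(analysis):
    res, samples = _psi_result_for({"AC_E01_r1": 50.0, "AC_E01_r2": 50.0}, analysis)
    pvals = pd.Series({"e1": 0.2})
    assert len(filter_reliable_events(res, samples, analysis, pvalues=pvals)) == 0


# --------------------------------------------------------------- pan / variant

def test_pan_variant_examples():
    cfg = AnalysisConfig(min_defined_samples=10)
    psi = pd.DataFrame(
        [[50.0] * 10,                       # active in 10/10 -> Pan
         [50.0] * 8 + [2.0, 98.0],          # active in 8/10 = 80% -> NOT Pan (strict)
         [30.0, 60.0] + [45.0] * 8,         # range 30 -> Variant
         [40.0, 50.0] + [45.0] * 8],        # range 10 -> not Variant
        index=["pan", "edge", "var", "flat"],
        columns=[f"s{i}" for i in range(10)],
    )
    labels = classify_pan_variant(psi, cfg)
    assert labels.loc["pan", "pan"] and not labels.loc["edge", "pan"]
    assert labels.loc["var", "variant"] and not labels.loc["flat", "variant"]


def test_pan_variant_matches_enumeration_oracle():
    """All 3^5 patterns of {low, active, high} over 5 samples."""
    cfg = AnalysisConfig(min_defined_samples=5, pan_fraction=0.80, variant_delta=25.0)
    levels = {"low": 2.0, "active": 50.0, "high": 98.0}
    import itertools
    patterns = list(itertools.product(levels.values(), repeat=5))
    psi = pd.DataFrame(patterns, columns=[f"s{i}" for i in range(5)])
    labels = classify_pan_variant(psi, cfg)
    for i, pat in enumerate(patterns):
        active = sum(5.0 < v < 95.0 for v in pat)
        assert labels.loc[i, "pan"] == (active / 5 > 0.80)
        assert labels.loc[i, "variant"] == (max(pat) - min(pat) > 25.0)


def test_all_na_event_gets_no_labels():
    psi = pd.DataFrame([[np.nan] * 4], index=["e"], columns=list("abcd"))
    labels = classify_pan_variant(psi, AnalysisConfig())
    assert not labels.loc["e", "pan"] and not labels.loc["e", "variant"]


# ------------------------------------------------------------------- profiles

def test_event_type_profile_proportions():
    cat = pd.DataFrame(
        {"event_type": ["A3", "A3", "RI", "RI"], "subgenome": ["A"] * 4},
        index=[f"e{i}" for i in range(4)],
    )
    prof = event_type_profile(cat)
    assert prof.loc["all", "A3"] == pytest.approx(0.5)
    assert prof.loc["all", "RI"] == pytest.approx(0.5)
    assert prof.loc["all", "n"] == 4
    one = event_type_profile(cat.iloc[:1])
    assert one.loc["all", "A3"] == pytest.approx(1.0)


def test_planted_event_type_mixture_recovered():
    """Primary-event type proportions match the configured mixture within
    multinomial error on a large synthetic catalog."""
    from polyas.config import SimulationConfig
    from polyas.simulate import simulate_dataset
    cfg = SimulationConfig(n_triads=1700, rng_seed=4)
    ds = simulate_dataset(cfg)
    truth = ds.truth.triads
    prof = event_type_profile(
        ds.catalog.loc[ds.catalog.index.isin(
            set(truth["event_A"]) | set(truth["event_B"]) | set(truth["event_D"])
        )]
    )
    mix = np.asarray(cfg.event_type_mixture)
    mix = mix / mix.sum()
    n = 3 * cfg.n_triads
    for p, etype in zip(mix, ("A3", "A5", "RI", "SE", "AF", "AL", "MX")):
        se = np.sqrt(p * (1 - p) / cfg.n_triads)  # types are shared within a triad
        assert abs(prof.loc["all", etype] - p) < 4 * se + 1e-9


# ------------------------------------------------------------ gene aggregation

def test_aggregate_gene_tpm_sums_and_expression_flag():
    quant = _quant_from({"t1": [3.0, 0.4], "t2": [4.0, 0.4]})
    samples = make_sample_table(2).iloc[:2]
    quant.tpm.columns = samples.index
    genes = aggregate_gene_tpm(quant, samples)
    assert genes.loc["g1", samples.index[0]] == pytest.approx(7.0)
    assert bool(genes.loc["g1", "expressed"])
    low = _quant_from({"t1": [0.4, 0.4], "t2": [0.4, 0.4]})
    low.tpm.columns = samples.index
    assert not bool(aggregate_gene_tpm(low, samples).loc["g1", "expressed"])


def test_aggregate_matches_naive_oracle():
    rng = np.random.default_rng(9)
    quant, _ = make_random_quant_catalog(rng, n_events=20, n_samples=6)
    samples = make_sample_table(2).iloc[:6]
    quant.tpm.columns = samples.index
    genes = aggregate_gene_tpm(quant, samples)
    for gid, grp in quant.transcripts.groupby("gene_id"):
        expected = quant.tpm.loc[grp.index].sum()
        assert np.allclose(genes.loc[gid, samples.index], expected)
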