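"""Percent-spliced-in (PSI) quantification and event-level classification.

PSI of an event in a sample is 100 x sum(TPM of inclusion transcripts) /
sum(TPM of all event transcripts), undefined (NA) when the event's total TPM
falls below ``min_event_tpm`` — the only read-coverage proxy available
downstream of transcript quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import EVENT_TYPES, TranscriptQuant


@dataclass
class PSIResult:
    """Events x samples PSI with the per-cell total event TPM as provenance."""

    psi: pd.DataFrame
    total_tpm: pd.DataFrame


def _sum_over(quant: TranscriptQuant, members: pd.Series) -> np.ndarray:
    """Sum TPM rows over per-event transcript tuples -> (n_events, n_samples)."""
    pos = {t: i for i, t in enumerate(quant.tpm.index)}
    values = quant.tpm.to_numpy()
    out = np.zeros((len(members), values.shape[1]))
    for row, tids in enumerate(members):
        for t in tids:
            if t not in pos:
                raise KeyError(t)
            out[row] += values[pos[t]]
    return out


def compute_psi(
    quant: TranscriptQuant, catalog: pd.DataFrame, config: AnalysisConfig | None = None
) -> PSIResult:
    """Compute the PSI matrix for every event in the catalog.

    Raises ``KeyError`` naming the event when an event references a
    transcript absent from the quantification table.
    """
    config = config or AnalysisConfig()
    try:
        inc = _sum_over(quant, catalog["inclusion"])
        tot = _sum_over(quant, catalog["total"])
    except KeyError as exc:
        missing = exc.args[0]
        bad = [
            eid for eid, row in catalog.iterrows()
            if missing in row["total"] or missing in row["inclusion"]
        ]
        raise KeyError(f"event(s) {bad} reference unknown transcript {missing!r}") from exc
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = 100.0 * inc / tot
    psi[tot < config.min_event_tpm] = np.nan
    cols = quant.tpm.columns
    return PSIResult(
        psi=pd.DataFrame(psi, index=catalog.index, columns=cols),
        total_tpm=pd.DataFrame(tot, index=catalog.index, columns=cols),
    )


def stage_mean_psi(psi: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean PSI per (variety, stage_tissue); NaN-aware.

    Columns become a MultiIndex (variety, stage_tissue).
    """
    tmp = psi.copy()
    tmp.columns = pd.MultiIndex.from_arrays(
        [samples.loc[psi.columns, "variety"], samples.loc[psi.columns, "stage_tissue"]],
        names=["variety", "stage_tissue"],
    )
    return tmp.T.groupby(level=["variety", "stage_tissue"]).mean().T


def filter_reliable_events(
    psi_result: PSIResult,
    samples: pd.DataFrame,
    config: AnalysisConfig | None = None,
    pvalues: pd.Series | None = None,
) -> pd.Index:
    """Keep events with replicate-mean PSI strictly inside the reliability
    window for at least one (variety, stage/tissue) group.

    ``pvalues`` is an optional per-event differential-splicing significance
    column; when given, events with p >= alpha are dropped as well.
    """
    config = config or AnalysisConfig()
    means = stage_mean_psi(psi_result.psi, samples)
    inside = (means > config.psi_reliable_low) & (means < config.psi_reliable_high)
    keep = inside.any(axis=1)
    if pvalues is not None:
        keep &= pvalues.reindex(keep.index) < config.alpha
    return keep.index[keep]


def classify_pan_variant(
    psi: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Label events as PanAS and/or VariantAS (not mutually exclusive).

    PanAS: strictly more than ``pan_fraction`` of the non-NA samples have PSI
    strictly inside the reliability window, with at least
    ``min_defined_samples`` non-NA samples.  VariantAS: the PSI range over
    non-NA samples exceeds ``variant_delta``.  All-NA events get both labels
    False.
    """
    config = config or AnalysisConfig()
    values = psi.to_numpy()
    defined = ~np.isnan(values)
    n_defined = defined.sum(axis=1)
    active = defined & (values > config.psi_reliable_low) & (values < config.psi_reliable_high)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_active = np.where(n_defined > 0, active.sum(axis=1) / np.maximum(n_defined, 1), 0.0)
    pan = (frac_active > config.pan_fraction) & (n_defined >= config.min_defined_samples)
    with np.errstate(all="ignore"):
        rng = np.nanmax(np.where(defined, values, -np.inf), axis=1) - np.nanmin(
            np.where(defined, values, np.inf), axis=1
        )
    rng = np.where(n_defined > 0, rng, 0.0)
    variant = rng > config.variant_delta
    return pd.DataFrame(
        {
            "pan": pan,
            "variant": variant,
            "n_defined": n_defined,
            "frac_active": frac_active,
            "psi_range": rng,
        },
        index=psi.index,
    )


def event_type_profile(
    catalog: pd.DataFrame, group_by: str | pd.Series | None = None
) -> pd.DataFrame:
    """Proportion of each AS event type, overall or per group.

    ``group_by`` may be a catalog column name (e.g. ``"subgenome"``) or an
    event-indexed label Series.  Returns one row per group with one column
    per event type plus a total count ``n``; proportions sum to 1 per row
    (NA row for an empty group).
    """
    if group_by is None:
        groups = pd.Series("all", index=catalog.index)
    elif isinstance(group_by, str):
        groups = catalog[group_by]
    else:
        groups = group_by.reindex(catalog.index)
    counts = (
        pd.crosstab(groups, catalog["event_type"])
        .reindex(columns=list(EVENT_TYPES), fill_value=0)
    )
    n = counts.sum(axis=1)
    props = counts.div(n.where(n > 0), axis=0)
    props["n"] = n
    return props


def aggregate_gene_tpm(
    quant: TranscriptQuant, samples: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Sum transcript TPM to the gene level (exact summation).

    Returns genes x samples TPM with an ``expressed`` flag column appended:
    a gene is expressed when its replicate-mean TPM exceeds 1 in at least one
    (variety, stage/tissue).
    """
    config = config or AnalysisConfig()
    gene_ids = quant.transcripts["gene_id"]
    if gene_ids.isna().any():
        raise ValueError("transcript without a gene_id")
    gene_tpm = quant.tpm.groupby(gene_ids).sum()
    means = stage_mean_psi(gene_tpm, samples)  # same replicate-mean machinery
    expressed = (means > 1.0).any(axis=1)
    out = gene_tpm.copy()
    out["expressed"] = expressed
    return out
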