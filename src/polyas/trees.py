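"""Triad-level GE/AS correlation divergence and PSI expression trees.

Gene-level conservation is Pearson r on homoeolog TPM trajectories across the
embryo stages; transcript-level divergence is Spearman rho on PSI.  Per-stage
neighbor-joining trees over (variety x subgenome) leaves use d = 1 - r
distances on triad-event PSI vectors; total branch length, bootstrapped over
triad events, summarizes inter-subgenome splicing divergence.  Duncan's
multiple range test compares the bootstrap length distributions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.decomposition import PCA

from .config import AnalysisConfig
from .io import EMBRYO_STAGES

MIN_SHARED_EVENTS = 20  # per leaf pair, for a stable correlation


# ---------------------------------------------------------------------------
# Triad correlations

def _pairwise(values: np.ndarray, func) -> dict[str, float]:
    out = {}
    for (i, a), (j, b) in itertools.combinations(enumerate("ABD"), 2):
        x, y = values[i], values[j]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or np.ptp(x[ok]) < 1e-9 or np.ptp(y[ok]) < 1e-9:
            out[f"{a}{b}"] = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[f"{a}{b}"] = float(func(x[ok], y[ok])[0])
    return out


def triad_correlations(
    triads: pd.DataFrame,
    gene_stage_means: pd.DataFrame,
    psi_stage_means: pd.DataFrame,
    variety: str = "AC",
    stages: tuple[str, ...] = EMBRYO_STAGES,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Pairwise homoeolog correlations per triad across embryo stages.

    Pearson r on gene TPM and Spearman rho on PSI for each of the three
    within-triad pairs; ``ge_conserved`` requires all three r above
    ``ge_conservation_r``, ``as_divergent`` requires at least one rho below
    ``as_divergence_rho``.  Correlations with fewer than 4 paired points are
    NA (and never satisfy either flag).
    """
    config = config or AnalysisConfig()
    gm = gene_stage_means[variety][list(stages)]
    pm = psi_stage_means[variety][list(stages)]
    rows = []
    for tid, row in triads.iterrows():
        tpm = np.vstack([gm.reindex([row[f"gene_{s}"]]).to_numpy()[0] for s in "ABD"])
        psi = np.vstack([pm.reindex([row[f"event_{s}"]]).to_numpy()[0] for s in "ABD"])
        r = _pairwise(tpm, stats.pearsonr)
        rho = _pairwise(psi, stats.spearmanr)
        rec = {"triad_id": tid}
        rec.update({f"r_{k}": v for k, v in r.items()})
        rec.update({f"rho_{k}": v for k, v in rho.items()})
        rvals = np.array(list(r.values()))
        rhovals = np.array(list(rho.values()))
        rec["ge_conserved"] = bool(np.isfinite(rvals).all() and (rvals > config.ge_conservation_r).all())
        rec["as_divergent"] = bool((rhovals[np.isfinite(rhovals)] < config.as_divergence_rho).any())
        rows.append(rec)
    return pd.DataFrame(rows).set_index("triad_id")


def conserved_ge_divergent_as(correlations: pd.DataFrame) -> pd.Index:
    """Triads with conserved gene expression and divergent splicing."""
    mask = correlations["ge_conserved"] & correlations["as_divergent"]
    return correlations.index[mask]


# ---------------------------------------------------------------------------
# Distance matrices and neighbor joining

def leaf_psi_matrix(
    psi_stage_means: pd.DataFrame,
    triads: pd.DataFrame,
    leaves: list[tuple[str, str]],
    stage: str,
) -> pd.DataFrame:
    """Leaves x triad-events PSI matrix for one stage/tissue.

    Each leaf is a (variety, subgenome) pair; its vector holds the PSI of the
    triad member event on that subgenome, indexed by triad so vectors are
    comparable across leaves.
    """
    data = {}
    for variety, subg in leaves:
        col = psi_stage_means[variety][stage]
        data[f"{variety}_{subg}"] = col.reindex(triads[f"event_{subg}"]).to_numpy()
    return pd.DataFrame(data, index=triads.index).T


def subgenome_distance_matrix(
    leaf_matrix: pd.DataFrame, method: str = "one_minus_r"
) -> DistanceMatrix | None:
    """Pairwise leaf distances from triad-event PSI vectors.

    Primary definition d = 1 - Pearson r (pairwise-complete); the flagged
    alternative is the Euclidean distance between rows of the leaf x leaf
    correlation matrix.  Returns ``None`` when any leaf pair shares fewer
    than ``MIN_SHARED_EVENTS`` defined events (the stage is skipped).
    Constant vectors raise: their correlation is undefined.
    """
    ids = list(leaf_matrix.index)
    values = leaf_matrix.to_numpy()
    n = len(ids)
    corr = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        ok = np.isfinite(values[i]) & np.isfinite(values[j])
        if ok.sum() < MIN_SHARED_EVENTS:
            return None
        x, y = values[i][ok], values[j][ok]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant PSI vector for leaf pair {ids[i]}, {ids[j]}")
        corr[i, j] = corr[j, i] = np.corrcoef(x, y)[0, 1]
    if method == "one_minus_r":
        dist = 1.0 - corr
    elif method == "euclidean_corr":
        dist = np.sqrt(((corr[:, None, :] - corr[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown distance method: {method!r}")
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids)


def neighbor_joining(dm: DistanceMatrix):
    """Classic Saitou-Nei NJ tree from a distance matrix (skbio TreeNode)."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    return nj(dm)


def total_tree_length(tree) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse() if not n.is_root()))


def tree_distance(tree, a: str, b: str) -> float:
    """Path length between two leaves of an NJ tree."""
    return float(tree.find(a).distance(tree.find(b)))


def bootstrap_tree_lengths(
    leaf_matrix: pd.DataFrame,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    method: str = "one_minus_r",
) -> np.ndarray:
    """Distribution of total NJ tree lengths over event-bootstrap replicates.

    Triad events (columns) are resampled with replacement ``n_bootstrap``
    times; each replicate rebuilds the distance matrix and NJ tree and
    records the total branch length.  Deterministic given the rng seed.
    Replicates whose resample leaves a pair with too few shared events or a
    constant vector are recorded as NaN.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    n_events = leaf_matrix.shape[1]
    if n_events < 2:
        raise ValueError("bootstrap needs at least 2 triad events")
    lengths = np.empty(config.n_bootstrap)
    for b in range(config.n_bootstrap):
        idx = rng.integers(0, n_events, size=n_events)
        sub = leaf_matrix.iloc[:, idx]
        try:
            dm = subgenome_distance_matrix(sub, method=method)
        except ValueError:
            dm = None
        lengths[b] = total_tree_length(neighbor_joining(dm)) if dm is not None else np.nan
    return lengths


# ---------------------------------------------------------------------------
# Duncan's multiple range test

def _duncan_critical(p: int, df: int, alpha: float) -> float:
    """Duncan's least significant studentized range for a stretch of p means.

    Uses Duncan's protection level alpha_p = 1 - (1 - alpha)^(p - 1) with the
    studentized range distribution.
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_mrt(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test with a compact letter display.

    ``groups`` maps labels to 1-D samples (>= 2 groups, >= 2 observations
    each).  The step-down procedure tests the range of every stretch of
    consecutive ordered means against Duncan's protected critical value
    (harmonic-mean n for unbalanced groups); a stretch inside a
    non-significant stretch is never declared significant.  Groups sharing a
    letter do not differ at the protected level.  With zero within-group
    variance, any two unequal means are significantly different.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("each group needs at least two observations")
    means = {k: v.mean() for k, v in data.items()}
    ns = {k: len(v) for k, v in data.items()}
    df = sum(ns.values()) - len(labels)
    mse = sum(((v - means[k]) ** 2).sum() for k, v in data.items()) / df
    n_h = len(labels) / sum(1.0 / n for n in ns.values())
    se = np.sqrt(mse / n_h)

    order = sorted(labels, key=lambda k: means[k], reverse=True)
    k = len(order)
    m = np.array([means[g] for g in order])

    # step-down: stretch (i..j) of p ordered means is non-significant when its
    # range is within Duncan's critical value, or when a containing stretch is.
    nonsig = np.zeros((k, k), dtype=bool)
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            covered = any(
                nonsig[i2, j2]
                for i2 in range(0, i + 1)
                for j2 in range(j, k)
                if (i2, j2) != (i, j) and j2 - i2 > j - i
            )
            if covered or (m[i] - m[j]) <= _duncan_critical(p, df, alpha) * se:
                nonsig[i, j] = True

    # compact letters from maximal non-significant stretches (incl. singletons)
    stretches = []
    for i in range(k):
        for j in range(i, k):
            if i == j or nonsig[i, j]:
                if not any(i2 <= i and j <= j2 and (i2, j2) != (i, j) and (i2 == j2 or nonsig[i2, j2])
                           for i2 in range(k) for j2 in range(i2, k)):
                    stretches.append((i, j))
    stretches.sort()
    letters = {g: "" for g in order}
    for s, (i, j) in enumerate(stretches):
        ch = chr(ord("a") + s)
        for idx in range(i, j + 1):
            letters[order[idx]] += ch

    return pd.DataFrame(
        {
            "group": order,
            "mean": [means[g] for g in order],
            "n": [ns[g] for g in order],
            "letters": [letters[g] for g in order],
        }
    ).set_index("group")


def duncan_any_significant(result: pd.DataFrame) -> bool:
    """True when some pair of groups shares no letter."""
    letters = result["letters"].tolist()
    return any(
        not (set(a) & set(b)) for a, b in itertools.combinations(letters, 2)
    )


# ---------------------------------------------------------------------------
# PCA plumbing

def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance fractions from an events/genes x samples matrix.

    Rows with missing values are dropped; samples are the observations.
    """
    complete = matrix.dropna(axis=0)
    if complete.empty:
        raise ValueError("no complete rows for PCA")
    x = complete.T.to_numpy()
    n_components = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
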