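"""Bray-Curtis distances, principal coordinates, and PERMANOVA.

The group-separation analysis works on the sample x sample Bray-Curtis
dissimilarity matrix

    d(u, v) = sum_i |u_i - v_i| / sum_i (u_i + v_i)

computed over proteins, with missing abundances treated as zeros (the only
policy currently offered; absence of quantification is read as absence of
signal for distance purposes).  Principal coordinates analysis is classical
scaling: Gower double-centering of -d^2/2 followed by a symmetric
eigendecomposition; axes are returned only for positive eigenvalues, and
negative eigenvalues are reported untouched (no Cailliez/Lingoes
correction).  PERMANOVA uses Anderson's one-way pseudo-F with a
label-permutation null; when the number of distinct two-group relabelings
fits within the permutation budget the null is enumerated exhaustively,
otherwise relabelings are sampled uniformly and the standard
(1 + more-extreme) / (1 + permutations) estimate is reported, so p never
reaches zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "bray_curtis",
    "pcoa",
    "permanova",
    "between_group_distance_summary",
    "PcoaResult",
    "PermanovaResult",
]


@dataclass
class PcoaResult:
    """Classical-scaling coordinates with their eigenvalue spectrum."""

    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: pd.Series  # over the positive-eigenvalue total


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "exhaustive" or "sampled"


def bray_curtis(matrix: pd.DataFrame, missing_policy: str = "as_zero") -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples (matrix columns)."""
    if missing_policy != "as_zero":
        raise ValueError("only the 'as_zero' missing policy is supported")
    X = matrix.fillna(0.0).to_numpy(dtype=float).T  # samples x proteins
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    ids = [str(c) for c in matrix.columns]
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1 :]).sum(axis=1)
        tot = (X[i] + X[i + 1 :]).sum(axis=1)
        zero = tot == 0
        if zero.any():
            j = i + 1 + int(np.flatnonzero(zero)[0])
            raise ValueError(f"distance undefined for all-zero sample pair ({ids[i]}, {ids[j]})")
        D[i, i + 1 :] = diff / tot
    D = D + D.T
    return DistanceMatrix(D, ids=ids)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering."""
    D = dist.data
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * n * np.finfo(float).eps
    pos = eigvals > tol
    if not pos.any():
        warnings.warn("all samples identical: no positive eigenvalues, empty coordinates")
        coords = pd.DataFrame(index=list(dist.ids))
        return PcoaResult(coords, eigvals, pd.Series(dtype=float))
    axes = [f"PC{k + 1}" for k in range(int(pos.sum()))]
    coords = pd.DataFrame(
        eigvecs[:, pos] * np.sqrt(eigvals[pos]), index=list(dist.ids), columns=axes
    )
    prop = pd.Series(eigvals[pos] / eigvals[pos].sum(), index=axes, name="proportion_explained")
    return PcoaResult(coords, eigvals, prop)


def _group_indicators(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique labels and a one-hot (groups x samples) indicator matrix."""
    uniq, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((uniq.size, labels.size))
    Z[inv, np.arange(labels.size)] = 1.0
    return uniq, Z


def _pseudo_f(D2: np.ndarray, Z: np.ndarray, ss_total: float, n_groups: int) -> np.ndarray:
    """Pseudo-F for a stack of group-indicator matrices.

    ``Z`` has shape (m, groups, n); within-group sums of squared distances
    are z D2 z^T / 2 per group, scaled by group size.
    """
    sizes = Z.sum(axis=2)  # m x groups
    ssw = np.einsum("mgi,ij,mgj->mg", Z, D2, Z) / 2.0 / sizes
    ss_within = ssw.sum(axis=1)
    n = D2.shape[0]
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` maps sample ids to labels (mapping or pandas Series) or is a
    sequence aligned with ``dist.ids``.  Every group needs at least two
    members.  Two-group designs whose distinct relabelings number at most
    ``n_permutations`` are enumerated exhaustively (p = fraction of
    relabelings at least as extreme, the observed one included).
    """
    ids = list(dist.ids)
    if hasattr(groups, "get") or isinstance(groups, pd.Series):
        labels = np.array([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(ids):
            raise ValueError("group labels do not align with distance matrix samples")
    uniq, Z0 = _group_indicators(labels)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = Z0.sum(axis=1)
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than two samples: {small}")

    D2 = dist.data**2
    n = len(ids)
    ss_total = D2.sum() / 2.0 / n
    if ss_total <= 0:
        raise ValueError("constant distance matrix: pseudo-F undefined")
    f_obs = float(_pseudo_f(D2, Z0[None, :, :], ss_total, uniq.size)[0])

    def _n_extreme(f_perm: np.ndarray) -> int:
        # an infinite observed F (zero within-group scatter) is matched only
        # by other infinite permuted F values
        if np.isinf(f_obs):
            return int(np.count_nonzero(np.isposinf(f_perm)))
        return int(np.count_nonzero(f_perm >= f_obs - 1e-12 * max(1.0, abs(f_obs))))

    n1 = int(counts[0])
    n_distinct = math.comb(n, n1) if uniq.size == 2 else None
    if n_distinct is not None and n_distinct <= n_permutations:
        Z = np.zeros((n_distinct, 2, n))
        for m, idx in enumerate(combinations(range(n), n1)):
            Z[m, 0, list(idx)] = 1.0
        Z[:, 1, :] = 1.0 - Z[:, 0, :]
        f_perm = _pseudo_f(D2, Z, ss_total, 2)
        p = _n_extreme(f_perm) / n_distinct
        return PermanovaResult(f_obs, p, n_distinct, seed, "exhaustive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    Z = np.empty((n_permutations, uniq.size, n))
    for m in range(n_permutations):
        Z[m] = Z0[:, rng.permutation(n)]
    f_perm = _pseudo_f(D2, Z, ss_total, uniq.size)
    p = (1.0 + _n_extreme(f_perm)) / (1.0 + n_permutations)
    return PermanovaResult(f_obs, p, n_permutations, seed, "sampled")


def between_group_distance_summary(dist: DistanceMatrix, groups) -> pd.DataFrame:
    """Five-number summaries of pairwise distances per group comparison.

    One row per within-group comparison (``g<->g``) and per unordered
    between-group pair (``g1<->g2``).  A comparison with no pairs (e.g. a
    singleton group's within-group row) is kept with ``n_pairs = 0`` and NaN
    statistics rather than silently reported as zero.
    """
    ids = list(dist.ids)
    if hasattr(groups, "get") or isinstance(groups, pd.Series):
        labels = np.array([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
    uniq = sorted(set(labels.tolist()))
    pools: dict[tuple[str, str], list[float]] = {}
    for g in uniq:
        pools[(g, g)] = []
    for g1, g2 in combinations(uniq, 2):
        pools[(g1, g2)] = []
    for i, j in combinations(range(len(ids)), 2):
        g1, g2 = sorted((labels[i], labels[j]))
        pools[(g1, g2)].append(dist.data[i, j])

    rows = []
    for (g1, g2), vals in pools.items():
        stats = (
            [len(vals)]
            + (list(np.percentile(vals, [0, 25, 50, 75, 100])) if vals else [np.nan] * 5)
        )
        rows.append([f"{g1}<->{g2}", *stats])
    return pd.DataFrame(
        rows, columns=["comparison", "n_pairs", "min", "q1", "median", "q3", "max"]
    ).set_index("comparison")
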