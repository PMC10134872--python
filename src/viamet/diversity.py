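"""Alpha/beta diversity: Shannon, Simpson, Bray-Curtis, PCoA, ANOSIM.

Implemented to a fixed, reproducible contract: Shannon uses natural log
(base-2 optional), Simpson is the Gini-Simpson complement 1 - sum(p^2),
PCoA is classical (Torgerson) scaling with a deterministic axis-sign
convention, and ANOSIM permutes labels with a caller-supplied seed so the
permutation p-value is bit-for-bit reproducible. Distance matrices use
scikit-bio's ``DistanceMatrix`` container (symmetric, zero-diagonal,
id-labelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .errors import InvalidInputError, UndefinedRatioError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "IntraInterResult",
    "shannon",
    "simpson",
    "bray_curtis",
    "beta_diversity_matrix",
    "pcoa",
    "anosim",
    "intra_inter_comparison",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` is samples x axes; ``eigenvalues`` are the retained
    (nonnegative) eigenvalues in descending order; ``proportion_explained``
    normalises them by the total positive eigenvalue mass. Negative
    eigenvalues (non-Euclidean distances) are dropped and their magnitude is
    reported in ``negative_eigenvalue_mass``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float = 0.0


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM rank statistic R in [-1, 1] and its permutation p-value."""

    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class IntraInterResult:
    """Within-host vs between-host pairwise-distance comparison."""

    intra: np.ndarray
    inter: np.ndarray
    median_intra: float
    median_inter: float
    p_value: float
    degenerate: bool = False


def _clean_composition(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidInputError("composition must be a nonempty 1-D vector")
    if (v < 0).any():
        raise InvalidInputError("composition entries must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise InvalidInputError("composition sums to zero")
    return v / total


def shannon(p, base: float | None = None) -> float:
    """Shannon entropy H = -sum(p_i log p_i) over positive entries.

    Natural log by default (ecology-package convention); pass ``base=2``
    for bits. Input is renormalised, so raw counts are accepted.
    """
    v = _clean_composition(p)
    v = v[v > 0]
    h = float(-(v * np.log(v)).sum())
    return h / math.log(base) if base is not None else h


def simpson(p) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2), in [0, 1)."""
    v = _clean_composition(p)
    return float(1.0 - (v**2).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise InvalidInputError("inputs must be 1-D vectors on the same taxa")
    if (xv < 0).any() or (yv < 0).any():
        raise InvalidInputError("abundances must be nonnegative")
    denom = (xv + yv).sum()
    if denom == 0:
        raise UndefinedRatioError("both vectors are all-zero; distance undefined")
    return float(np.abs(xv - yv).sum() / denom)


def beta_diversity_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis over the columns (samples) of an abundance
    table; returns a labelled ``skbio.DistanceMatrix``."""
    ids = list(table.columns)
    n = len(ids)
    mat = np.zeros((n, n))
    cols = table.to_numpy(dtype=float).T
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(cols[i], cols[j])
    return DistanceMatrix(mat, ids)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal-coordinate analysis by classical scaling.

    Double-centres -D^2/2, eigendecomposes, and keeps the top ``n_axes``
    nonnegative eigenvalues. Each axis is oriented so its largest-magnitude
    coordinate is positive (deterministic sign convention). Coordinates for
    axes whose eigenvalue is (numerically) zero are zeroed.
    """
    n = d.shape[0]
    if not 0 < n_axes < n:
        raise InvalidInputError(f"n_axes must be in [1, {n - 1}], got {n_axes}")
    dm = d.data
    b = dm**2 * -0.5
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    negative_mass = float(-eigvals[eigvals < -tol].sum())
    eigvals = np.clip(eigvals, 0.0, None)
    kept = eigvals[:n_axes]
    coords = eigvecs[:, :n_axes] * np.sqrt(kept)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    total = eigvals.sum()
    prop = kept / total if total > 0 else np.zeros_like(kept)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PC{i + 1}" for i in range(n_axes)]
        ),
        eigenvalues=kept,
        proportion_explained=prop,
        negative_eigenvalue_mass=negative_mass,
    )


def _anosim_r(rank_mat: np.ndarray, within: np.ndarray) -> float:
    n = rank_mat.shape[0]
    m = n * (n - 1) / 2
    iu = np.triu_indices(n, k=1)
    r = rank_mat[iu]
    w = within[iu]
    return float((r[~w].mean() - r[w].mean()) / (m / 2.0))


def anosim(
    d: DistanceMatrix,
    labels: Sequence[str] | Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2 and average ranks for tied distances. The p-value is
    (1 + #{permuted R >= observed R}) / (1 + n_permutations) under random
    relabelling with a seeded generator.
    """
    ids = list(d.ids)
    if isinstance(labels, Mapping):
        grouping = np.array([labels[i] for i in ids])
    else:
        grouping = np.asarray(list(labels))
        if grouping.size != len(ids):
            raise InvalidInputError("labels length must match the distance matrix")
    uniq, counts = np.unique(grouping, return_counts=True)
    if uniq.size < 2:
        raise InvalidInputError("anosim needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise InvalidInputError(f"groups with fewer than 2 samples: {small}")
    n = len(ids)
    condensed_ranks = stats.rankdata(squareform(d.data, checks=False))
    rank_mat = squareform(condensed_ranks)
    within = grouping[:, None] == grouping[None, :]
    r_obs = _anosim_r(rank_mat, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(grouping)
        if _anosim_r(rank_mat, perm[:, None] == perm[None, :]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r_obs, float(p), n_permutations, seed)


def intra_inter_comparison(
    d: DistanceMatrix, host_labels: Sequence[str] | Mapping[str, str]
) -> IntraInterResult:
    """Partition all pairwise distances into within-host and between-host
    sets and compare them with a two-sided rank-sum (unpaired Wilcoxon) test.

    With degenerate input (all distances identical, e.g. all-zero) the test
    is undefined and p = 1 is reported with the ``degenerate`` flag.
    """
    ids = list(d.ids)
    if isinstance(host_labels, Mapping):
        hosts = np.array([host_labels[i] for i in ids])
    else:
        hosts = np.asarray(list(host_labels))
        if hosts.size != len(ids):
            raise InvalidInputError("host_labels length must match the matrix")
    if np.unique(hosts).size < 2:
        raise InvalidInputError("need >= 2 hosts to compare intra vs inter")
    iu = np.triu_indices(len(ids), k=1)
    same = (hosts[:, None] == hosts[None, :])[iu]
    dists = d.data[iu]
    intra, inter = dists[same], dists[~same]
    if intra.size == 0 or inter.size == 0:
        raise InvalidInputError("need both intra- and inter-host pairs")
    if np.ptp(dists) == 0:
        return IntraInterResult(
            intra, inter, float(np.median(intra)), float(np.median(inter)),
            p_value=1.0, degenerate=True,
        )
    p = float(stats.mannwhitneyu(intra, inter, alternative="two-sided").pvalue)
    return IntraInterResult(
        intra, inter, float(np.median(intra)), float(np.median(inter)), p
    )
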