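"""Two-block partial least squares: the shape-genetics integration model.

Given a shape block (the W' partial-warp matrix) and a genetic block (the
first two principal-coordinate axes of a genetic distance matrix), the
singular value decomposition of the between-block covariance matrix yields
ordered pairs of latent vectors maximising cross-block covariation.  The
correlation R of each paired latent-score series measures the integration
of shape with genetic divergence; its significance is assessed by
permuting specimens of one block, and the first-pair association is also
summarised by a linear fit (R^2) and a Spearman rank correlation for the
monotonic-trend reading.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class ParameterError(ValueError):
    pass


@dataclass
class PlsResult:
    shape_weights: np.ndarray  # (p, m) unit-norm columns
    genetic_weights: np.ndarray  # (q, m) unit-norm columns
    singular_values: np.ndarray  # (m,) descending
    pair_correlations: np.ndarray  # (m,) Pearson R per latent pair
    scores_block1: np.ndarray  # (n, m)
    scores_block2: np.ndarray  # (n, m)
    spearman_rho: float  # first latent pair, rank correlation
    permutation_p: Optional[np.ndarray] = None

    @property
    def n_pairs(self) -> int:
        return len(self.singular_values)

    @property
    def linear_r2(self) -> float:
        """Squared Pearson correlation of the first latent pair."""
        return float(self.pair_correlations[0] ** 2)

    def to_dict(self) -> dict:
        return {
            "shape_weights": self.shape_weights,
            "genetic_weights": self.genetic_weights,
            "singular_values": self.singular_values,
            "pair_correlations": self.pair_correlations,
            "linear_r2": self.linear_r2,
            "spearman_rho": self.spearman_rho,
            "scores_block1": self.scores_block1,
            "scores_block2": self.scores_block2,
            "permutation_p": self.permutation_p,
        }


def _center(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    return x - x.mean(axis=0)


def _standardize(x: np.ndarray) -> np.ndarray:
    xc = _center(x)
    sd = xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant columns contribute zero either way
    return xc / sd


def two_block_pls(
    block1: np.ndarray,
    block2: np.ndarray,
    mode: str = "covariance",
) -> PlsResult:
    """SVD of the between-block covariance (or correlation) matrix.

    Latent pairs are ordered by singular value; scores are projections of
    the centred blocks on the unit-norm weight vectors, and
    ``pair_correlations`` are the Pearson correlations of paired scores.
    ``mode="correlation"`` standardises columns first (the blocks' scaling
    is otherwise left as given, the TPSPLS convention).
    """
    x1 = np.asarray(block1, float)
    x2 = np.asarray(block2, float)
    if x1.ndim == 1:
        x1 = x1[:, None]
    if x2.ndim == 1:
        x2 = x2[:, None]
    n = x1.shape[0]
    if x2.shape[0] != n:
        raise ValueError("blocks must share the specimen roster")
    if n < 3:
        raise ValueError("need at least 3 specimens")
    if mode == "covariance":
        c1, c2 = _center(x1), _center(x2)
    elif mode == "correlation":
        c1, c2 = _standardize(x1), _standardize(x2)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    cov = c1.T @ c2 / (n - 1)
    u, s, vt = np.linalg.svd(cov, full_matrices=False)
    m = min(c1.shape[1], c2.shape[1])
    u, s, v = u[:, :m], s[:m], vt[:m].T
    scores1 = c1 @ u
    scores2 = c2 @ v
    corrs = np.zeros(m)
    for j in range(m):
        s1, s2 = scores1[:, j], scores2[:, j]
        denom = s1.std(ddof=1) * s2.std(ddof=1)
        corrs[j] = float(np.cov(s1, s2, ddof=1)[0, 1] / denom) if denom > 0 else 0.0
    # fix signs so each pair correlates positively (weight pairs are sign-ambiguous)
    for j in range(m):
        if corrs[j] < 0:
            v[:, j] = -v[:, j]
            scores2[:, j] = -scores2[:, j]
            corrs[j] = -corrs[j]
    rho = float(stats.spearmanr(scores1[:, 0], scores2[:, 0]).statistic) if n > 2 else 0.0
    return PlsResult(
        shape_weights=u,
        genetic_weights=v,
        singular_values=s,
        pair_correlations=corrs,
        scores_block1=scores1,
        scores_block2=scores2,
        spearman_rho=rho,
    )


def _pair_stats(c1: np.ndarray, c2: np.ndarray, n: int) -> tuple:
    cov = c1.T @ c2 / (n - 1)
    u, s, vt = np.linalg.svd(cov, full_matrices=False)
    m = min(c1.shape[1], c2.shape[1])
    scores1 = c1 @ u[:, :m]
    scores2 = c2 @ vt[:m].T
    corrs = np.zeros(m)
    for j in range(m):
        d = scores1[:, j].std(ddof=1) * scores2[:, j].std(ddof=1)
        corrs[j] = abs(float(np.cov(scores1[:, j], scores2[:, j], ddof=1)[0, 1] / d)) if d > 0 else 0.0
    return s[:m], corrs


def pls_permutation_test(
    block1: np.ndarray,
    block2: np.ndarray,
    statistic: str = "R",
    n_perm: int = 999,
    seed: int = 0,
    exhaustive_max_n: int = 7,
) -> np.ndarray:
    """Permutation p-values per latent pair (one-sided, upper tail).

    Rows of ``block2`` are permuted; p = (1 + #{permuted statistic >=
    observed}) / (n_perm + 1).  ``statistic`` is the latent-pair
    correlation ``"R"`` or the singular value ``"covariance"``.  For
    n <= ``exhaustive_max_n`` all n! permutations are enumerated instead
    and p is an exact fraction over the full permutation distribution.
    """
    if statistic not in ("R", "covariance"):
        raise ParameterError(f"unknown statistic {statistic!r}; expected 'R' or 'covariance'")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    x1 = np.atleast_2d(np.asarray(block1, float))
    x2 = np.asarray(block2, float)
    if x2.ndim == 1:
        x2 = x2[:, None]
    n = x1.shape[0]
    c1, c2 = _center(x1), _center(x2)
    pick = 0 if statistic == "covariance" else 1
    obs = _pair_stats(c1, c2, n)[pick]
    m = len(obs)
    if n <= exhaustive_max_n:
        hits = np.zeros(m)
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = _pair_stats(c1, c2[list(perm)], n)[pick]
            hits += stat >= obs - 1e-12
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = np.zeros(m)
    for _ in range(n_perm):
        stat = _pair_stats(c1, c2[rng.permutation(n)], n)[pick]
        hits += stat >= obs
    return (1 + hits) / (n_perm + 1)


@dataclass
class IntegrationReport:
    """Group-level summary of the latent space and outlier flags."""

    labels: list  # group names
    group_centroids_block1: np.ndarray  # (g, m)
    group_centroids_block2: np.ndarray  # (g, m)
    spread_ratios: np.ndarray  # (m,) between/within spread per latent axis
    flagged: list  # specimen ids on the wrong latent-1 half-plane

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "group_centroids_block1": self.group_centroids_block1,
            "group_centroids_block2": self.group_centroids_block2,
            "spread_ratios": self.spread_ratios,
            "flagged": self.flagged,
        }


def integration_report(
    pls: PlsResult,
    labels: Sequence[str],
    specimen_ids: Optional[Sequence[str]] = None,
) -> IntegrationReport:
    """Per-group latent-space centroids, spread ratios and outlier flags.

    A specimen is flagged when its genetic latent-1 score falls on the
    opposite side of the grand mean from its labelled group's majority —
    the signature of a specimen whose genotype disagrees with its
    morphology-based identification.
    """
    labels = list(labels)
    n = pls.scores_block1.shape[0]
    if len(labels) != n:
        raise ValueError("label count does not match fitted specimens")
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(n)]
    names = sorted(set(labels))
    s1, s2 = pls.scores_block1, pls.scores_block2
    cent1 = np.stack([s1[[i for i, l in enumerate(labels) if l == g]].mean(axis=0) for g in names])
    cent2 = np.stack([s2[[i for i, l in enumerate(labels) if l == g]].mean(axis=0) for g in names])
    m = s1.shape[1]
    ratios = np.zeros(m)
    combined = (s1 + s2) / 2.0
    for j in range(m):
        within = 0.0
        between = 0.0
        grand = combined[:, j].mean()
        for gi, g in enumerate(names):
            rows = [i for i, l in enumerate(labels) if l == g]
            gm = combined[rows, j].mean()
            within += ((combined[rows, j] - gm) ** 2).sum()
            between += len(rows) * (gm - grand) ** 2
        ratios[j] = between / within if within > 0 else np.inf
    flagged = []
    if len(names) > 1:
        axis1 = s2[:, 0] - s2[:, 0].mean()
        for g in names:
            rows = [i for i, l in enumerate(labels) if l == g]
            majority = np.sign(np.median(np.sign(axis1[rows])))
            if majority == 0:
                continue  # group straddles the axis; no meaningful flag
            for i in rows:
                if np.sign(axis1[i]) != 0 and np.sign(axis1[i]) != majority:
                    flagged.append(specimen_ids[i])
    return IntegrationReport(
        labels=names,
        group_centroids_block1=cent1,
        group_centroids_block2=cent2,
        spread_ratios=ratios,
        flagged=flagged,
    )
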