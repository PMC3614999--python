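"""Group discrimination: canonical variate analysis and classification trees.

Two complementary classifiers support the species-delimitation question:

* :func:`fit_cva` — canonical variate analysis on shape variables,
  maximising between-group relative to within-group variance, with
  Mahalanobis distances between group means, a permutation test on those
  distances and a leave-one-out cross-validation of group assignment.
* :func:`fit_crt` — a classification tree (greedy binary Gini
  partitioning) over the six meristic counts, yielding a reproducible
  dichotomous species identification key.

When the pooled within-group covariance is rank deficient (p > n - g, the
usual situation for partial-warp data), features are first projected onto
their pooled principal components with eigenvalue > 1e-10, the standard
practice in geometric morphometrics software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import MERISTIC_CHARACTERS, MeristicRecord


class RankDeficiencyError(ValueError):
    """Within-group covariance singular even after principal-component reduction."""


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Canonical variate analysis


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray  # (g, g) true x assigned

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def overall_correct_pct(self) -> float:
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else float("nan")

    @property
    def per_group_misclassified_pct(self) -> np.ndarray:
        row_tot = self.counts.sum(axis=1)
        correct = np.diag(self.counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * (row_tot - correct) / row_tot

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "counts": self.counts,
            "overall_correct_pct": self.overall_correct_pct,
            "per_group_misclassified_pct": self.per_group_misclassified_pct,
        }


@dataclass
class CvaResult:
    labels: list  # group names, fixed order
    canonical_axes: np.ndarray  # (p, n_axes) coefficient vectors
    scores: np.ndarray  # (n, n_axes)
    eigenvalues: np.ndarray
    group_means: np.ndarray  # (g, n_axes) canonical-space means
    mahalanobis: np.ndarray  # (g, g) distances between group means
    permutation_p: Optional[np.ndarray] = None
    procrustes_group_distance: Optional[np.ndarray] = None

    @property
    def n_axes(self) -> int:
        return self.canonical_axes.shape[1]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "canonical_axes": self.canonical_axes,
            "scores": self.scores,
            "eigenvalues": self.eigenvalues,
            "group_means": self.group_means,
            "mahalanobis": self.mahalanobis,
            "permutation_p": self.permutation_p,
            "procrustes_group_distance": self.procrustes_group_distance,
        }


def _group_indices(labels: Sequence) -> tuple:
    labels = list(labels)
    names = sorted(set(labels))
    idx = {name: [i for i, l in enumerate(labels) if l == name] for name in names}
    return names, idx


def _pca_reduce(x: np.ndarray, tol: float = 1e-10, max_components: Optional[int] = None) -> tuple:
    """Project centred data onto principal components with eigenvalue > tol.

    ``max_components`` additionally caps the dimensionality (set to n - g by
    callers so the pooled within-group covariance stays full rank).
    """
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / max(x.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    keep = np.where(evals > tol)[0][::-1]  # descending by eigenvalue
    if max_components is not None:
        keep = keep[:max_components]
    proj = evecs[:, keep]
    return xc @ proj, proj


def _pooled_within(x: np.ndarray, names, idx) -> tuple:
    n, g = x.shape[0], len(names)
    means = np.stack([x[idx[name]].mean(axis=0) for name in names])
    sw = np.zeros((x.shape[1], x.shape[1]))
    for gi, name in enumerate(names):
        centred = x[idx[name]] - means[gi]
        sw += centred.T @ centred
    sw /= n - g
    return means, sw


def fit_cva(features: np.ndarray, labels: Sequence) -> CvaResult:
    """Canonical variate analysis of grouped multivariate data.

    Solves the between/within generalized eigenproblem using the pooled
    within-group covariance (divisor n - g); axes are scaled so pooled
    within-group variance of each canonical score is 1 and ordered by
    decreasing eigenvalue.  Mahalanobis distances between group means are
    computed in the full within-group metric, not just the retained axes.
    """
    x = np.asarray(features, float)
    names, idx = _group_indices(labels)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if len(idx[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    n, g = x.shape[0], len(names)
    if n - g < 1:
        raise ValueError("need n - g >= 1 residual degrees of freedom")
    xr, proj = _pca_reduce(x, max_components=n - g)
    means, sw = _pooled_within(xr, names, idx)
    evals_w, evecs_w = np.linalg.eigh(sw)
    if np.min(evals_w) <= 1e-12 * max(np.max(evals_w), 1.0):
        raise RankDeficiencyError(
            "pooled within-group covariance is singular; reduce dimensionality "
            "(fewer features or more specimens per group)"
        )
    whiten = evecs_w @ np.diag(evals_w**-0.5) @ evecs_w.T
    grand = np.zeros(xr.shape[1])  # xr already centred on grand mean
    sizes = np.array([len(idx[name]) for name in names], float)
    dev = means - grand
    sb = (dev.T * sizes) @ dev / (g - 1)
    m = whiten @ sb @ whiten
    evals_b, evecs_b = np.linalg.eigh(m)
    order = np.argsort(evals_b)[::-1]
    n_axes = min(g - 1, xr.shape[1])
    u = evecs_b[:, order[:n_axes]]
    axes_r = whiten @ u  # within-variance of scores = 1 by construction
    scores = xr @ axes_r
    group_means = means @ axes_r
    swinv = whiten @ whiten
    maha = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = means[i] - means[j]
            maha[i, j] = maha[j, i] = float(np.sqrt(d @ swinv @ d))
    return CvaResult(
        labels=names,
        canonical_axes=proj @ axes_r,
        scores=scores,
        eigenvalues=np.maximum(evals_b[order[:n_axes]], 0.0),
        group_means=group_means,
        mahalanobis=maha,
    )


def _mahalanobis_assign(train_x, train_labels, test_x):
    """Assign test rows to the nearest group mean in the pooled within metric."""
    names, idx = _group_indices(train_labels)
    xr, proj = _pca_reduce(train_x, max_components=train_x.shape[0] - len(names))
    mean_shift = train_x.mean(axis=0)
    means, sw = _pooled_within(xr, names, idx)
    evals_w, evecs_w = np.linalg.eigh(sw)
    keep = evals_w > 1e-12 * max(np.max(evals_w), 1.0)
    whiten = evecs_w[:, keep] @ np.diag(evals_w[keep] ** -0.5)
    tw = (test_x - mean_shift) @ proj @ whiten
    mw = means @ whiten
    d2 = ((tw[:, None, :] - mw[None, :, :]) ** 2).sum(axis=2)
    return [names[j] for j in d2.argmin(axis=1)]


def loo_crossvalidate_cva(features: np.ndarray, labels: Sequence) -> ConfusionMatrix:
    """Leave-one-out cross-validated group assignment.

    Each specimen is assigned to the group whose mean is nearest in the
    Mahalanobis metric of the discriminant refitted without that specimen.
    The superimposition (or any other upstream step) is not refitted.
    """
    x = np.asarray(features, float)
    names, idx = _group_indices(labels)
    for name in names:
        if len(idx[name]) < 2:
            raise ValueError(f"group {name!r} has size 1; cannot leave out and refit")
    labels = list(labels)
    n = x.shape[0]
    name_pos = {name: i for i, name in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        assigned = _mahalanobis_assign(x[mask], [labels[j] for j in range(n) if j != i], x[i : i + 1])[0]
        counts[name_pos[labels[i]], name_pos[assigned]] += 1
    return ConfusionMatrix(labels=names, counts=counts)


def _pair_mahalanobis(x: np.ndarray, is_b: np.ndarray) -> float:
    """Squared Mahalanobis distance between two group means (pooled within cov)."""
    a = x[~is_b]
    b = x[is_b]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ca = a - ma
    cb = b - mb
    sw = (ca.T @ ca + cb.T @ cb) / (len(x) - 2)
    d = ma - mb
    evals, evecs = np.linalg.eigh(sw)
    keep = evals > 1e-12 * max(float(np.max(evals)), 1.0)
    dw = (d @ evecs[:, keep]) / np.sqrt(evals[keep])
    return float(dw @ dw)


def cva_permutation_test(
    features: np.ndarray,
    labels: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Pairwise permutation test on between-group Mahalanobis distances.

    For each group pair, labels are permuted within the pair ``n_perm``
    times; p = (1 + #{permuted distance >= observed}) / (n_perm + 1).
    Returns a symmetric g x g matrix with 1.0 on the diagonal.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    x = np.asarray(features, float)
    names, idx = _group_indices(labels)
    g = len(names)
    rng = np.random.default_rng(seed)
    pmat = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            rows = np.array(idx[names[i]] + idx[names[j]])
            nb = len(idx[names[j]])
            xp, _ = _pca_reduce(x[rows])
            is_b = np.zeros(len(rows), bool)
            is_b[-nb:] = True
            obs = _pair_mahalanobis(xp, is_b)
            hits = 0
            for _ in range(n_perm):
                hits += _pair_mahalanobis(xp, rng.permutation(is_b)) >= obs
            pmat[i, j] = pmat[j, i] = (1 + hits) / (n_perm + 1)
    return pmat


# ---------------------------------------------------------------------------
# Classification tree on meristic counts


@dataclass
class CrtNode:
    n: int
    class_counts: dict
    impurity: float
    label: str
    predictor: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["CrtNode"] = None
    right: Optional["CrtNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "class_counts": self.class_counts,
            "impurity": self.impurity,
            "label": self.label,
        }
        if not self.is_leaf:
            d.update(
                predictor=self.predictor,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


@dataclass
class CrtTree:
    """Binary identification key over the six meristic counts.

    Internal nodes test ``predictor <= threshold`` (ties descend left);
    leaves carry the majority species of their training rows.
    """

    root: CrtNode
    predictors: tuple = MERISTIC_CHARACTERS
    cv: Optional[ConfusionMatrix] = None
    params: dict = field(default_factory=dict)

    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def depth(self) -> int:
        def walk(node):
            if node.is_leaf:
                return 0
            return 1 + max(walk(node.left), walk(node.right))

        return walk(self.root)

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "predictors": list(self.predictors),
            "cv": self.cv.to_dict() if self.cv else None,
            "params": self.params,
        }


def _gini(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts / tot
    return float(1.0 - (p**2).sum())


def best_split(x: np.ndarray, y: np.ndarray, predictors: Sequence[str], min_child: int):
    """Exhaustive search for the Gini-optimal binary split.

    Evaluates every predictor and every midpoint between consecutive
    observed values; ties in impurity decrease are broken by predictor
    order, then by the lower threshold, so trees are deterministic.
    Returns ``(predictor_index, threshold, decrease)`` or ``None``.
    """
    classes, y_idx = np.unique(y, return_inverse=True)
    total = np.bincount(y_idx, minlength=len(classes)).astype(float)
    n = len(y)
    parent_gini = _gini(total)
    best = None
    best_dec = 1e-12  # require a strictly positive decrease
    for pi in range(x.shape[1]):
        vals = x[:, pi]
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        sy = y_idx[order]
        left = np.zeros(len(classes))
        for cut in range(1, n):
            left[sy[cut - 1]] += 1
            if sv[cut] == sv[cut - 1]:
                continue
            nl = cut
            nr = n - cut
            if nl < min_child or nr < min_child:
                continue
            dec = parent_gini - (nl * _gini(left) + nr * _gini(total - left)) / n
            if dec > best_dec + 1e-12:
                best_dec = dec
                best = (pi, (sv[cut - 1] + sv[cut]) / 2.0, dec)
    return best


def fit_crt(
    records: Sequence[MeristicRecord],
    labels: Optional[Sequence[str]] = None,
    min_parent: int = 10,
    min_child: int = 5,
    max_depth: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
) -> CrtTree:
    """Grow a classification tree over the six meristic counts.

    Greedy binary recursive partitioning by Gini impurity decrease;
    splitting stops at pure nodes, nodes smaller than ``min_parent`` or
    depth ``max_depth``, and splits leaving a child below ``min_child``
    are not considered.  A stratified ``cv_folds``-fold cross-validated
    confusion matrix is attached (set ``cv_folds=0`` to skip).
    """
    if min_child >= min_parent:
        raise ParameterError("min_child must be smaller than min_parent")
    if labels is None:
        labels = [r.taxon for r in records]
        if any(l is None for l in labels):
            raise ValueError("records lack taxon labels and none were supplied")
    labels = np.asarray(labels, dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes")
    x = np.array([[r[c] for c in MERISTIC_CHARACTERS] for r in records], dtype=float)
    if np.all(x.max(axis=0) == x.min(axis=0)):
        raise ValueError("all predictors are constant; no tree can be grown")

    def grow(rows: np.ndarray, depth: int) -> CrtNode:
        yv = labels[rows]
        classes, counts = np.unique(yv, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        node = CrtNode(
            n=len(rows),
            class_counts={str(c): int(k) for c, k in zip(classes, counts)},
            impurity=_gini(counts.astype(float)),
            label=str(classes[order[0]]),
        )
        if len(classes) == 1 or len(rows) < min_parent or depth >= max_depth:
            return node
        found = best_split(x[rows], yv, MERISTIC_CHARACTERS, min_child)
        if found is None:
            return node
        pi, thr, _ = found
        node.predictor = MERISTIC_CHARACTERS[pi]
        node.threshold = thr
        go_left = x[rows, pi] <= thr
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    tree = CrtTree(
        root=grow(np.arange(len(records)), 0),
        params=dict(
            min_parent=min_parent, min_child=min_child, max_depth=max_depth,
            cv_folds=cv_folds, seed=seed,
        ),
    )
    if cv_folds:
        tree.cv = crossvalidate_crt(
            records, labels, min_parent=min_parent, min_child=min_child,
            max_depth=max_depth, cv_folds=cv_folds, seed=seed,
        )
    return tree


def crossvalidate_crt(
    records, labels, min_parent=10, min_child=5, max_depth=5, cv_folds=10, seed=0
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation of the meristic tree.

    ``cv_folds="loo"`` performs leave-one-out instead.
    """
    from sklearn.model_selection import LeaveOneOut, StratifiedKFold

    labels = np.asarray(labels, dtype=object)
    names = sorted(set(labels))
    name_pos = {n: i for i, n in enumerate(names)}
    counts = np.zeros((len(names), len(names)), int)
    if cv_folds == "loo":
        splitter = LeaveOneOut().split(np.zeros(len(labels)))
    else:
        smallest = min(np.unique(labels, return_counts=True)[1])
        folds = min(int(cv_folds), int(smallest))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed).split(
            np.zeros(len(labels)), labels
        )
    records = list(records)
    for train, test in splitter:
        sub = fit_crt(
            [records[i] for i in train], labels[train],
            min_parent=min_parent, min_child=min_child, max_depth=max_depth,
            cv_folds=0, seed=seed,
        )
        for i in test:
            assigned = predict_crt(sub, records[i])
            counts[name_pos[labels[i]], name_pos[assigned]] += 1
    return ConfusionMatrix(labels=names, counts=counts)


def predict_crt(tree: CrtTree, record: MeristicRecord) -> str:
    """Descend the key: ``x <= t`` goes left; return the leaf's species label."""
    node = tree.root
    while not node.is_leaf:
        if node.predictor not in record.counts:
            raise KeyError(f"record lacks predictor {node.predictor!r}")
        node = node.left if record[node.predictor] <= node.threshold else node.right
    return node.label


def key_text(tree: CrtTree) -> str:
    """Render the tree as a human-readable dichotomous identification key."""
    lines = []

    def walk(node, prefix):
        if node.is_leaf:
            lines.append(f"{prefix}-> {node.label}  (n={node.n}, counts={node.class_counts})")
            return
        lines.append(f"{prefix}{node.predictor} <= {node.threshold:g}?")
        walk(node.left, prefix + "  yes: ")
        walk(node.right, prefix + "  no:  ")

    walk(tree.root, "")
    return "\n".join(lines) + "\n"
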