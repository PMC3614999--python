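"""Alignment summaries, genetic distances and principal coordinate analysis.

The molecular side of the pipeline works on small multiple-sequence
alignments (mitochondrial cyt b, nuclear RAG1 and the non-coding Cyfun P
region) and produces the summaries used for species attribution: variable
site counts, haplotype collapses, pairwise identities, fixed diagnostic
differences between taxa (substitutions classified as transitions or
transversions, plus shared indel blocks), amplicon band-length attribution,
uncorrected (or JC69/K2P-corrected) distance matrices, and a principal
coordinate embedding of those distances.

Site-handling conventions: a column is variable when it shows at least two
distinct states among {A,C,G,T}; variation involving only N is ignored; a
column containing gaps but a single base is not variable, while a column
with two or more bases is variable regardless of gaps.  Pairwise
comparisons skip positions where either sequence has a gap or N.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io import SeqEntry, SequenceSet

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_BASES = ("A", "C", "G", "T")


class UndefinedIdentityError(ValueError):
    """No comparable (gap- and N-free) positions shared by the two sequences."""


def _matrix(aln: SequenceSet) -> np.ndarray:
    if not aln.aligned:
        raise ValueError("input sequences are not aligned (unequal lengths)")
    return aln.matrix()


# ---------------------------------------------------------------------------
# Variable sites and haplotypes


def count_variable_sites(aln: SequenceSet) -> dict:
    """Count alignment columns with >= 2 distinct bases among {A,C,G,T}.

    Returns ``{"variable": v, "length": L, "pct": 100 * v / L}`` with the
    percentage rounded to one decimal place.
    """
    mat = _matrix(aln)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    variable = 0
    for col in mat.T:
        states = set(col) & set(_BASES)
        if len(states) >= 2:
            variable += 1
    length = mat.shape[1]
    return {"variable": variable, "length": length, "pct": round(100.0 * variable / length, 1)}


@dataclass
class Haplotype:
    residues: str
    multiplicity: int
    members: list


@dataclass
class HaplotypeSet:
    marker: str
    haplotypes: list

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "haplotypes": [
                {"residues": h.residues, "multiplicity": h.multiplicity, "members": h.members}
                for h in self.haplotypes
            ],
        }


def collapse_haplotypes(aln: SequenceSet) -> HaplotypeSet:
    """Collapse identical rows (exact match, upper-cased; N is a distinct state)."""
    _matrix(aln)  # validates alignment
    seen: dict = {}
    order: list = []
    for e in aln.entries:
        res = e.residues.upper()
        if res not in seen:
            seen[res] = []
            order.append(res)
        seen[res].append(e.specimen_id)
    haps = [Haplotype(residues=r, multiplicity=len(seen[r]), members=seen[r]) for r in order]
    return HaplotypeSet(marker=aln.marker, haplotypes=haps)


# ---------------------------------------------------------------------------
# Pairwise identity and similarity summaries


def _needleman_wunsch(a: str, b: str) -> tuple:
    """Global alignment with match +1, mismatch -1, gap open -5, extend -1."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alignment = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_identity(a: Union[str, SeqEntry], b: Union[str, SeqEntry], mode: str = "aligned") -> float:
    """Percent identity between two sequences.

    Positions where either sequence has a gap (or an N) are excluded from
    both numerator and denominator.  ``mode="global_align"`` first aligns
    the ungapped sequences by Needleman-Wunsch (match +1, mismatch -1, gap
    open -5, extend -1).
    """
    sa = a.residues if isinstance(a, SeqEntry) else a
    sb = b.residues if isinstance(b, SeqEntry) else b
    sa, sb = sa.upper(), sb.upper()
    if mode == "global_align":
        sa, sb = _needleman_wunsch(sa, sb)
    elif mode != "aligned":
        raise ValueError(f"unknown mode {mode!r}")
    if len(sa) != len(sb):
        raise ValueError("aligned mode requires equal-length sequences")
    matches = compared = 0
    for x, y in zip(sa, sb):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        matches += x == y
    if compared == 0:
        raise UndefinedIdentityError("no comparable positions shared by the two sequences")
    return 100.0 * matches / compared


def similarity_summary(aln: SequenceSet) -> dict:
    """Within- and between-taxon percent-identity summaries.

    Because it is ambiguous whether a reported group "similarity" is a
    mean, minimum or maximum over sequence pairs, all three are returned
    for every within-group and between-group comparison.
    """
    groups: dict = {}
    for e in aln.entries:
        groups.setdefault(e.taxon, []).append(e)
    out = {"within": {}, "between": {}}
    for taxon, members in groups.items():
        vals = [
            pairwise_identity(x, y)
            for x, y in itertools.combinations(members, 2)
        ]
        if vals:
            out["within"][taxon] = {
                "mean": float(np.mean(vals)), "min": float(np.min(vals)), "max": float(np.max(vals)),
            }
    for ta, tb in itertools.combinations(sorted(groups), 2):
        vals = [pairwise_identity(x, y) for x in groups[ta] for y in groups[tb]]
        out["between"][f"{ta}|{tb}"] = {
            "mean": float(np.mean(vals)), "min": float(np.min(vals)), "max": float(np.max(vals)),
        }
    return out


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray
    metric_tag: str = "p-distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dict(self) -> dict:
        return {"ids": self.ids, "values": self.values, "metric_tag": self.metric_tag}


def _encode(aln: SequenceSet) -> tuple:
    mat = _matrix(aln)
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[mat == b] = i
    valid = codes >= 0
    return codes, valid


def _pair_counts(codes, valid, i, j):
    both = valid[i] & valid[j]
    compared = int(both.sum())
    diffs = int(((codes[i] != codes[j]) & both).sum())
    return diffs, compared


def _correct(p: float, ts: float, tv: float, metric: str) -> float:
    if metric == "p":
        return p
    if metric == "jc":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise ValueError(f"p-distance {p} too large for Jukes-Cantor correction")
        return -0.75 * np.log(arg)
    if metric == "k2p":
        a1 = 1.0 - 2.0 * ts - tv
        a2 = 1.0 - 2.0 * tv
        if a1 <= 0 or a2 <= 0:
            raise ValueError("distances too large for Kimura two-parameter correction")
        return -0.5 * np.log(a1 * np.sqrt(a2))
    raise ValueError(f"unknown metric {metric!r}; expected p, jc or k2p")


def p_distance_matrix(
    aln: Union[SequenceSet, Sequence[SequenceSet]],
    metric: str = "p",
    weights: Optional[Sequence[float]] = None,
) -> DistanceMatrix:
    """Pairwise distance matrix from one or more alignments.

    Default metric is the uncorrected p-distance (proportion of differing
    compared sites; gaps and N excluded pairwise); ``jc`` and ``k2p``
    corrections are available.  When several marker alignments are given
    they must share the specimen roster and are combined by a (by default
    unweighted) average per pair.
    """
    alns = [aln] if isinstance(aln, SequenceSet) else list(aln)
    ids = [e.specimen_id for e in alns[0].entries]
    for other in alns[1:]:
        if [e.specimen_id for e in other.entries] != ids:
            raise ValueError("specimen rosters differ across marker alignments")
    if weights is None:
        weights = [1.0] * len(alns)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    n = len(ids)
    total = np.zeros((n, n))
    for w, a in zip(weights, alns):
        codes, valid = _encode(a)
        is_purine = (codes == 0) | (codes == 2)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                compared = int(both.sum())
                if compared == 0:
                    raise UndefinedIdentityError(
                        f"no comparable sites between {ids[i]} and {ids[j]}"
                    )
                diff = (codes[i] != codes[j]) & both
                p = diff.sum() / compared
                ts = (diff & (is_purine[i] == is_purine[j])).sum() / compared
                tv = p - ts
                d[i, j] = d[j, i] = _correct(p, ts, tv, metric)
        total += w * d
    tag = metric + ("" if len(alns) == 1 else f" (mean of {len(alns)} markers)")
    return DistanceMatrix(ids=ids, values=total, metric_tag=tag)


# ---------------------------------------------------------------------------
# Diagnostic differences


@dataclass
class DiagnosticDifferences:
    """Fixed differences between two taxon groups in an alignment.

    ``substitutions`` holds ``(position, state_a, state_b, class)`` tuples
    (0-based column, class "transition" or "transversion");
    ``indels`` holds maximal gap blocks as ``(start, length, group_lacking)``.
    """

    group_a: str
    group_b: str
    substitutions: list
    indels: list

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "substitutions": [
                {"position": p, "state_a": a, "state_b": b, "class": c}
                for p, a, b, c in self.substitutions
            ],
            "indels": [
                {"start": s, "length": l, "group_lacking": g} for s, l, g in self.indels
            ],
        }


def substitution_class(x: str, y: str) -> str:
    if (x in PURINES) == (y in PURINES):
        return "transition"
    return "transversion"


def diagnostic_differences(aln: SequenceSet, group_a: str, group_b: str) -> DiagnosticDifferences:
    """Columns fixed for different bases in two groups, plus shared indels.

    A substitution column requires every member of each group to carry a
    single base (no N, no gap) and the two groups' bases to differ.  An
    indel block is a maximal run of columns gapped in every member of one
    group and occupied by a base in every member of the other.
    """
    mat = _matrix(aln)
    taxa = np.asarray(aln.taxa())
    rows_a = np.where(taxa == group_a)[0]
    rows_b = np.where(taxa == group_b)[0]
    if len(rows_a) == 0:
        raise ValueError(f"group label {group_a!r} absent from alignment")
    if len(rows_b) == 0:
        raise ValueError(f"group label {group_b!r} absent from alignment")
    subs = []
    gap_state = []  # per column: None, group_a (a gapped) or group_b (b gapped)
    for pos in range(mat.shape[1]):
        col_a = set(mat[rows_a, pos])
        col_b = set(mat[rows_b, pos])
        base_a = col_a.pop() if len(col_a) == 1 else None
        base_b = col_b.pop() if len(col_b) == 1 else None
        if base_a in _BASES and base_b in _BASES and base_a != base_b:
            subs.append((pos, base_a, base_b, substitution_class(base_a, base_b)))
        if base_a == "-" and base_b in _BASES:
            gap_state.append(group_a)
        elif base_b == "-" and base_a in _BASES:
            gap_state.append(group_b)
        else:
            gap_state.append(None)
    indels = []
    pos = 0
    ncol = len(gap_state)
    while pos < ncol:
        owner = gap_state[pos]
        if owner is None:
            pos += 1
            continue
        start = pos
        while pos < ncol and gap_state[pos] == owner:
            pos += 1
        indels.append((start, pos - start, owner))
    return DiagnosticDifferences(group_a=group_a, group_b=group_b, substitutions=subs, indels=indels)


# ---------------------------------------------------------------------------
# Band-length attribution


DEFAULT_BAND_KEY = {
    "T. muticellus": (295, 325),
    "Squalius": (395, 425),
    "R. rubilio": (425.5, 455),
}


def band_length_attribution(length_bp: int, key: Optional[dict] = None) -> str:
    """Assign an amplicon band length to a taxon (or genus) by interval key.

    The default key reflects the diagnostic band lengths of the Cyfun P
    region: ~310 bp for T. muticellus, ~440 bp for R. rubilio and an
    intermediate ~410 bp shared by the two Squalius species (attribution
    to genus only), each with a +/-15 bp window.  Lengths outside every
    interval return ``"unassigned"``.
    """
    if length_bp <= 0:
        raise ValueError("band length must be positive")
    key = dict(DEFAULT_BAND_KEY if key is None else key)
    intervals = sorted(key.items(), key=lambda kv: kv[1][0])
    for (la, ia), (lb, ib) in zip(intervals, intervals[1:]):
        if ia[1] >= ib[0]:
            raise ValueError(f"band intervals for {la!r} and {lb!r} overlap")
    for label, (lo, hi) in intervals:
        if lo <= length_bp <= hi:
            return label
    return "unassigned"


# ---------------------------------------------------------------------------
# Principal coordinate analysis


@dataclass
class PcoaResult:
    ids: list
    coordinates: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # all n, descending
    negative_eigenvalue_sum: float
    correction: str = "none"

    def to_dict(self) -> dict:
        return {
            "ids": self.ids,
            "coordinates": self.coordinates,
            "eigenvalues": self.eigenvalues,
            "negative_eigenvalue_sum": self.negative_eigenvalue_sum,
            "correction": self.correction,
        }


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def pcoa(dm: DistanceMatrix, correction: str = "none", n_axes: Optional[int] = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double-centering of -1/2 D^2, eigendecomposition, coordinates =
    eigenvectors scaled by the square roots of the positive eigenvalues.
    ``correction`` may be ``"lingoes"`` or ``"cailliez"`` to remove
    negative eigenvalues; if none are present the correction is skipped
    with a log notice.  Axis signs are fixed so each axis's
    largest-magnitude loading is positive.
    """
    d = dm.values.copy()
    n = d.shape[0]
    tol = 1e-9 * max(1.0, float(np.abs(d).max()) ** 2)
    b = _gower_center(d)
    evals = np.linalg.eigvalsh(b)
    tag = "none"
    if correction != "none":
        if evals.min() >= -tol:
            logger.info("correction %r requested but no negative eigenvalues; skipping", correction)
        elif correction == "lingoes":
            c = -evals.min()
            d2 = d**2 + 2 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
            tag = "lingoes"
        elif correction == "cailliez":
            delta1 = _gower_center(d)
            delta2 = -0.5 * (np.eye(n) - np.ones((n, n)) / n) @ d @ (np.eye(n) - np.ones((n, n)) / n)
            block = np.zeros((2 * n, 2 * n))
            block[:n, n:] = 2 * delta1
            block[n:, :n] = -np.eye(n)
            block[n:, n:] = -4 * delta2
            c = float(np.max(np.linalg.eigvals(block).real))
            d = d + c
            np.fill_diagonal(d, 0.0)
            tag = "cailliez"
        else:
            raise ValueError(f"unknown correction {correction!r}")
        b = _gower_center(d)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    positive = evals > tol
    coords = evecs[:, positive] * np.sqrt(evals[positive])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    if n_axes is not None:
        if coords.shape[1] < n_axes:
            pad = np.zeros((n, n_axes - coords.shape[1]))
            coords = np.hstack([coords, pad])
        coords = coords[:, :n_axes]
    return PcoaResult(
        ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=evals,
        negative_eigenvalue_sum=float(evals[evals < -tol].sum()),
        correction=tag,
    )
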