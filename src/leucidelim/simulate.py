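"""Synthetic four-species datasets with planted, parameter-controlled truth.

The generator emulates the structure of a four-species sympatric study
sample: landmark configurations drawn around species mean shapes (one
species with twice the within-group spread), species-specific overlapping
meristic count ranges, and per-marker sequence sets evolved from a common
ancestor down a fixed little tree (the two congeneric species share a
clade ancestor, so their sequences are mutually closest).  Because every
dataset is built from known parameters, each pipeline stage can be tested
against planted ground truth: which predictor separates species, how many
haplotypes exist, where the diagnostic indel lies, and (for the integrated
dataset) the analytic first-pair PLS correlation between shape and genetic
divergence.

Default group sizes are (65, 26, 27, 27) and default species templates are
four 21-landmark fish outlines differing in body depth, dorsal-fin
position and caudal-peduncle height, stored as a versioned TPS fixture.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    MERISTIC_CHARACTERS,
    MeristicRecord,
    SeqEntry,
    SequenceSet,
    TpsRecord,
    read_tps,
    write_fasta,
    write_json,
    write_meristic_csv,
    write_tps,
)
from .morphometry import LandmarkConfiguration, centroid_size, gpa_align, bending_energy_basis

_BASES = np.array(list("ACGT"))

MARKER_LENGTHS = {"cytb": 1131, "rag1": 840, "cyfunp": 452}

DEFAULT_GROUP_SIZES = {"Sl": 65, "Ss": 26, "Tm": 27, "Rr": 27}


@dataclass
class SpeciesTemplate:
    """Generator parameters for one species.

    ``divergence`` is the per-marker substitution probability on the
    species' own branch; species sharing a ``clade`` first inherit a clade
    ancestor mutated from the root at ``clade_divergence``.  ``indel_blocks``
    lists (start, length) alignment blocks deleted in this species
    (Cyfun P only by default).
    """

    name: str
    mean_shape: np.ndarray  # (k, 2) centred, unit centroid size
    shape_noise_sd: float = 0.004
    shape_spread_multiplier: float = 1.0
    meristic_ranges: dict = field(default_factory=dict)  # char -> (lo, hi) inclusive
    clade: Optional[str] = None
    divergence: dict = field(default_factory=dict)  # marker -> tip probability
    clade_divergence: dict = field(default_factory=dict)  # marker -> shared probability
    indel_blocks: dict = field(default_factory=dict)  # marker -> [(start, length)]

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, float)
        if self.shape_noise_sd <= 0 or self.shape_spread_multiplier <= 0:
            raise ValueError("noise sd and spread multiplier must be positive")
        for marker, p in self.divergence.items():
            if not 0 <= p <= 0.25:
                raise ValueError(f"divergence for {marker} must be in [0, 0.25]")
        for char, (lo, hi) in self.meristic_ranges.items():
            if hi < lo:
                raise ValueError(f"empty meristic interval for {char}")


_DEFAULT_MERISTICS = {
    # intervals chosen so NSLL separates coarsely, NRAF and NRPF refine,
    # with enough overlap that cross-validated accuracy sits near 0.9
    "Rr": {"NSLL": (36, 41), "NSALL": (6, 8), "NSULL": (3, 4), "NRDF": (9, 11), "NRPF": (14, 16), "NRAF": (10, 12)},
    "Sl": {"NSLL": (40, 46), "NSALL": (7, 8), "NSULL": (3, 5), "NRDF": (10, 12), "NRPF": (15, 17), "NRAF": (8, 10)},
    "Ss": {"NSLL": (43, 49), "NSALL": (7, 9), "NSULL": (4, 5), "NRDF": (10, 12), "NRPF": (16, 18), "NRAF": (10, 11)},
    "Tm": {"NSLL": (47, 55), "NSALL": (8, 9), "NSULL": (4, 6), "NRDF": (10, 12), "NRPF": (13, 16), "NRAF": (9, 10)},
}

_DEFAULT_DIVERGENCE = {
    # tip-branch substitution probabilities per marker
    "Sl": {"cytb": 0.035, "rag1": 0.004, "cyfunp": 0.008},
    "Ss": {"cytb": 0.035, "rag1": 0.004, "cyfunp": 0.008},
    "Tm": {"cytb": 0.075, "rag1": 0.0075, "cyfunp": 0.025},
    "Rr": {"cytb": 0.078, "rag1": 0.008, "cyfunp": 0.025},
}

_SQUALIUS_CLADE_DIVERGENCE = {"cytb": 0.04, "rag1": 0.005, "cyfunp": 0.01}

_DEFAULT_INDELS = {
    # Cyfun P alignment blocks (start, length) deleted per species:
    # Tm has a short band (~310 bp), both Squalius an intermediate one
    # (~410 bp) and the Sl-like species an additional 17 bp 3'-terminal
    # deletion; the Rr-like species keeps the full ~450 bp band.
    "Sl": {"cyfunp": [(200, 42), (435, 17)]},
    "Ss": {"cyfunp": [(200, 42)]},
    "Tm": {"cyfunp": [(150, 142)]},
    "Rr": {"cyfunp": []},
}


def template_shapes() -> dict:
    """Load the versioned 21-landmark mean shapes (centred, unit size)."""
    with resources.as_file(resources.files("leucidelim").joinpath("data/template_shapes.tps")) as p:
        records = read_tps(p)
    out = {}
    for rec in records:
        coords = rec.coords - rec.coords.mean(axis=0)
        out[rec.specimen_id] = coords / centroid_size(coords)
    return out


def default_templates() -> list:
    """The four default species templates (order: Sl, Ss, Tm, Rr)."""
    shapes = template_shapes()
    out = []
    for name in ("Sl", "Ss", "Tm", "Rr"):
        out.append(
            SpeciesTemplate(
                name=name,
                mean_shape=shapes[name],
                shape_noise_sd=0.004,
                shape_spread_multiplier=2.0 if name == "Sl" else 1.0,
                meristic_ranges=dict(_DEFAULT_MERISTICS[name]),
                clade="Squalius" if name in ("Sl", "Ss") else None,
                divergence=dict(_DEFAULT_DIVERGENCE[name]),
                clade_divergence=dict(_SQUALIUS_CLADE_DIVERGENCE) if name in ("Sl", "Ss") else {},
                indel_blocks={m: list(b) for m, b in _DEFAULT_INDELS[name].items()},
            )
        )
    return out


def _specimen_ids(templates, n_per_species):
    ids = []
    for t, n in zip(templates, n_per_species):
        ids.extend(f"{t.name}{i + 1:02d}" for i in range(n))
    return ids


# ---------------------------------------------------------------------------
# Landmarks


def simulate_landmarks(
    templates: Sequence[SpeciesTemplate],
    n_per_species: Sequence[int],
    seed: int = 0,
) -> list:
    """Draw labelled landmark configurations around each species mean.

    Each specimen is the species mean plus isotropic Gaussian landmark
    noise (sd x spread multiplier), then arbitrarily rotated, translated
    and scaled to emulate digitised raw coordinates.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for t, n in zip(templates, n_per_species):
        if n < 2:
            raise ValueError("need at least 2 specimens per species")
        if centroid_size(t.mean_shape) <= 0:  # raises on degenerate input
            raise ValueError("degenerate mean shape")
        sd = t.shape_noise_sd * t.shape_spread_multiplier
        for i in range(n):
            shape = t.mean_shape + rng.normal(0.0, sd, size=t.mean_shape.shape)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            scale = rng.uniform(80.0, 120.0)
            shift = rng.uniform(100.0, 500.0, size=2)
            coords = shape @ rot.T * scale + shift
            configs.append(
                LandmarkConfiguration(specimen_id=f"{t.name}{i + 1:02d}", coords=coords, taxon=t.name)
            )
    return configs


# ---------------------------------------------------------------------------
# Meristic counts


def simulate_meristics(
    templates: Sequence[SpeciesTemplate],
    n_per_species: Sequence[int],
    seed: int = 0,
) -> list:
    """Draw each count uniformly from the species' configured interval."""
    rng = np.random.default_rng(seed)
    records = []
    for t, n in zip(templates, n_per_species):
        for char in MERISTIC_CHARACTERS:
            if char not in t.meristic_ranges:
                raise ValueError(f"template {t.name} lacks a range for {char}")
        for i in range(n):
            counts = {
                char: int(rng.integers(t.meristic_ranges[char][0], t.meristic_ranges[char][1] + 1))
                for char in MERISTIC_CHARACTERS
            }
            records.append(
                MeristicRecord(specimen_id=f"{t.name}{i + 1:02d}", counts=counts, taxon=t.name)
            )
    return records


# ---------------------------------------------------------------------------
# Sequences


def _mutate(seq: np.ndarray, p: float, rng) -> np.ndarray:
    """Substitute each site with probability p (uniform among other bases)."""
    out = seq.copy()
    hits = np.where(rng.random(len(seq)) < p)[0]
    for pos in hits:
        choices = [b for b in range(4) if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out


def _species_base_sequences(templates, marker, rng):
    """Root -> (clade ancestors) -> species base haplotypes, as int arrays."""
    length = MARKER_LENGTHS[marker]
    root = rng.integers(0, 4, size=length)
    clades: dict = {}
    bases = {}
    for t in templates:
        if t.clade is not None:
            if t.clade not in clades:
                clades[t.clade] = _mutate(root, t.clade_divergence.get(marker, 0.0), rng)
            parent = clades[t.clade]
        else:
            parent = root
        bases[t.name] = _mutate(parent, t.divergence.get(marker, 0.0), rng)
    return bases


def _to_residues(codes: np.ndarray, gap_blocks=()) -> str:
    chars = _BASES[codes].copy()
    for start, length in gap_blocks:
        chars[start : start + length] = "-"
    return "".join(chars)


def simulate_sequences(
    templates: Sequence[SpeciesTemplate],
    marker: str,
    n_per_species: Sequence[int],
    seed: int = 0,
    within_scale: float = 1.0,
) -> SequenceSet:
    """Evolve an aligned sequence set for one marker.

    Species base haplotypes descend from a shared ancestor (congeners via
    a clade ancestor); individuals carry the species haplotype with
    additional within-species variants at Bernoulli(divergence / 20 x
    ``within_scale``) sites.  Species-specific deletion blocks (Cyfun P)
    appear as gap columns, giving an alignment with the full ancestral
    coordinate system.
    """
    if marker not in MARKER_LENGTHS:
        raise ValueError(f"unknown marker {marker!r}")
    rng = np.random.default_rng(seed)
    bases = _species_base_sequences(templates, marker, rng)
    entries = []
    for t, n in zip(templates, n_per_species):
        gaps = t.indel_blocks.get(marker, [])
        p_within = t.divergence.get(marker, 0.0) / 20.0 * within_scale
        for i in range(n):
            codes = _mutate(bases[t.name], p_within, rng)
            entries.append(
                SeqEntry(
                    specimen_id=f"{t.name}{i + 1:02d}",
                    taxon=t.name,
                    residues=_to_residues(codes, gaps),
                )
            )
    return SequenceSet(marker=marker, entries=entries)


# ---------------------------------------------------------------------------
# Integrated dataset


@dataclass
class SyntheticDataset:
    """All components of one synthetic study sample, plus generator truth."""

    configs: list  # LandmarkConfiguration
    meristics: list  # MeristicRecord
    alignments: dict  # marker -> SequenceSet
    truth: dict

    def specimen_ids(self) -> list:
        return [c.specimen_id for c in self.configs]

    def labels(self) -> list:
        return [c.taxon for c in self.configs]


def simulate_dataset(
    templates: Optional[Sequence[SpeciesTemplate]] = None,
    n_per_species: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Independent landmark, meristic and sequence components, one roster."""
    if templates is None:
        templates = default_templates()
    if n_per_species is None:
        n_per_species = [DEFAULT_GROUP_SIZES[t.name] if t.name in DEFAULT_GROUP_SIZES else 20 for t in templates]
    ss = np.random.SeedSequence(seed)
    s_land, s_mer, s_cytb, s_rag1, s_cyf = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]
    configs = simulate_landmarks(templates, n_per_species, seed=s_land)
    meristics = simulate_meristics(templates, n_per_species, seed=s_mer)
    alignments = {
        "cytb": simulate_sequences(templates, "cytb", n_per_species, seed=s_cytb),
        "rag1": simulate_sequences(templates, "rag1", n_per_species, seed=s_rag1),
        "cyfunp": simulate_sequences(templates, "cyfunp", n_per_species, seed=s_cyf),
    }
    truth = {
        "seed": seed,
        "n_per_species": list(map(int, n_per_species)),
        "species": [t.name for t in templates],
        "shape_noise_sd": [t.shape_noise_sd for t in templates],
        "shape_spread_multiplier": [t.shape_spread_multiplier for t in templates],
    }
    return SyntheticDataset(configs=configs, meristics=meristics, alignments=alignments, truth=truth)


def simulate_integrated(
    templates: Optional[Sequence[SpeciesTemplate]] = None,
    n_per_species: Optional[Sequence[int]] = None,
    target_r: float = 0.9,
    seed: int = 0,
    shape_offset_scale: float = 0.04,
    within_scale: float = 1.0,
    planted_outlier: bool = False,
) -> SyntheticDataset:
    """Dataset whose shape-genetics covariation has a known first-pair R.

    Species mean shapes are constructed as a linear embedding of the
    species' genetic principal-coordinate centroids into shape tangent
    space (so pairwise Procrustes offsets are proportional to pairwise
    genetic distances, with overall scale ``shape_offset_scale``), and
    isotropic shape noise is calibrated analytically so the expected
    first-pair PLS correlation equals ``target_r``.  The analytic value
    and calibrated noise are recorded in ``truth``.  ``planted_outlier``
    swaps the sequences of the first specimen of the first species for
    sequences drawn from the last species' haplotype.
    """
    from .popgen import p_distance_matrix, pcoa

    if not 0 <= target_r <= 1:
        raise ValueError("target_r must be in [0, 1]")
    if templates is None:
        templates = default_templates()
    if n_per_species is None:
        n_per_species = [DEFAULT_GROUP_SIZES.get(t.name, 20) for t in templates]
    ss = np.random.SeedSequence(seed)
    s_cytb, s_rag1, s_cyf, s_mer, s_shape = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]
    alignments = {
        "cytb": simulate_sequences(templates, "cytb", n_per_species, seed=s_cytb, within_scale=within_scale),
        "rag1": simulate_sequences(templates, "rag1", n_per_species, seed=s_rag1, within_scale=within_scale),
        "cyfunp": simulate_sequences(templates, "cyfunp", n_per_species, seed=s_cyf, within_scale=within_scale),
    }
    labels = [e.taxon for e in alignments["cytb"].entries]
    ids = [e.specimen_id for e in alignments["cytb"].entries]
    outlier_id = None
    if planted_outlier:
        # replace the genetic rows of the first specimen of species 1 with a
        # within-species variant of the last species' haplotype (its
        # morphology keeps the original label) — the Sl14 scenario
        rng_out = np.random.default_rng(int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)))
        donor = templates[-1]
        outlier_id = ids[0]
        for marker in ("cytb", "rag1", "cyfunp"):
            donor_entry = next(e for e in alignments[marker].entries if e.taxon == donor.name)
            codes = np.array([" ACGT".index(c) - 1 if c != "-" else -1 for c in donor_entry.residues])
            nongap = codes >= 0
            mutated = codes.copy()
            mutated[nongap] = _mutate(
                codes[nongap], donor.divergence.get(marker, 0.0) / 20.0 * within_scale, rng_out
            )
            residues = "".join("-" if c < 0 else "ACGT"[c] for c in mutated)
            alignments[marker].entries[0] = SeqEntry(
                specimen_id=outlier_id, taxon=labels[0], residues=residues
            )
    dm = p_distance_matrix([alignments["cytb"], alignments["rag1"]])
    ord_res = pcoa(dm, n_axes=2)
    gscores = ord_res.coordinates  # (n, 2)
    names = [t.name for t in templates]
    rows = {name: [i for i, l in enumerate(labels) if l == name] for name in names}
    n = len(labels)
    centroids = {name: gscores[rows[name]].mean(axis=0) for name in names}
    gamma_c = np.stack([centroids[l] for l in labels])  # per-specimen species centroid
    gamma_c -= gamma_c.mean(axis=0)
    bcov = gamma_c.T @ gamma_c / (n - 1)
    evals_b, evecs_b = np.linalg.eigh(bcov)
    lam1 = float(evals_b[-1])
    b1 = evecs_b[:, -1]
    within = gscores - np.stack([centroids[l] for l in labels])
    w1 = float(b1 @ (within.T @ within / (n - 1)) @ b1)
    r_max = np.sqrt(lam1 / (lam1 + w1)) if lam1 + w1 > 0 else 0.0
    if target_r > r_max + 1e-12:
        raise ValueError(
            f"target_r={target_r} unattainable: genetic within-species scatter "
            f"caps the first-pair correlation at {r_max:.4f}"
        )
    # embed species genetic centroids into shape tangent space
    base = templates[0].mean_shape
    basis = bending_energy_basis(base)
    w = basis.nonuniform_warps()
    k = base.shape[0]
    p1 = np.stack([w[:, 0], np.zeros(k)], axis=1).reshape(-1)
    p2 = np.stack([np.zeros(k), w[:, 0]], axis=1).reshape(-1)
    pmat = np.stack([p1, p2], axis=1)  # (2k, 2) orthonormal tangent directions
    rms = np.sqrt((gamma_c**2).sum(axis=1).mean())
    c = shape_offset_scale / rms
    if target_r == 0:
        sigma = max(10.0 * c * np.sqrt(max(lam1, 1e-12)), 1e-3)
    else:
        sigma2 = (c**2) * lam1**2 / (target_r**2 * (lam1 + w1)) - (c**2) * lam1
        sigma = float(np.sqrt(max(sigma2, 0.0)))
    rng = np.random.default_rng(s_shape)
    configs = []
    for i, (sid, lab) in enumerate(zip(ids, labels)):
        offset = (pmat @ (c * gamma_c[i])).reshape(k, 2)
        shape = base + offset + rng.normal(0.0, sigma, size=(k, 2))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        scale = rng.uniform(80.0, 120.0)
        shift = rng.uniform(100.0, 500.0, size=2)
        configs.append(
            LandmarkConfiguration(specimen_id=sid, coords=shape @ rot.T * scale + shift, taxon=lab)
        )
    meristics = simulate_meristics(templates, n_per_species, seed=s_mer)
    analytic_r = (
        c * lam1 / np.sqrt((c**2 * lam1 + sigma**2) * (lam1 + w1)) if lam1 > 0 else 0.0
    )
    truth = {
        "seed": seed,
        "n_per_species": list(map(int, n_per_species)),
        "species": names,
        "target_r": target_r,
        "analytic_r": float(analytic_r),
        "attainable_r_max": float(r_max),
        "shape_noise_sd": sigma,
        "shape_offset_scale": shape_offset_scale,
        "planted_outlier": outlier_id,
    }
    return SyntheticDataset(configs=configs, meristics=meristics, alignments=alignments, truth=truth)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Serialise a dataset: landmarks.tps, meristics.csv, per-marker FASTA, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tps(
        [TpsRecord(specimen_id=c.specimen_id, coords=c.coords) for c in ds.configs],
        out / "landmarks.tps",
    )
    write_meristic_csv(ds.meristics, out / "meristics.csv")
    for marker, aln in ds.alignments.items():
        write_fasta(aln, out / f"{marker}.fasta")
    write_json(ds.truth, out / "truth.json")
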