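"""Readers and writers for the file formats used throughout the pipeline.

Three input formats are supported:

* **TPS landmark files** in the dialect written by the tpsDig digitising
  tool: ``LM=<k>`` starts a record, followed by ``k`` whitespace-separated
  ``x y`` coordinate lines (image pixels, y increasing upward), then
  optional ``ID=``, ``IMAGE=`` and ``SCALE=`` lines.
* **FASTA** alignments, read through Biopython.  The header convention is
  ``>specimenID|taxon``; the taxon part is optional and defaults to
  ``"unknown"``.
* **Meristic CSV** tables with the six count characters
  NSLL, NSALL, NSULL, NRDF, NRPF, NRAF and optional ``specimen_id`` /
  ``taxon`` columns.

Landmark indices are 1-based in files and documentation and 0-based in
memory; the conversion happens only here, at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MERISTIC_CHARACTERS = ("NSLL", "NSALL", "NSULL", "NRDF", "NRPF", "NRAF")
VALID_MARKERS = ("cytb", "rag1", "cyfunp")
VALID_RESIDUES = frozenset("ACGTN-")


class ParseError(ValueError):
    """Raised when an input file is malformed."""


class SchemaError(ValueError):
    """Raised when a table lacks required columns."""


@dataclass
class TpsRecord:
    """One specimen's raw digitised landmarks, in file (pixel) units."""

    specimen_id: str
    coords: np.ndarray  # (k, 2) float array, (x, y)
    scale: Optional[float] = None
    image: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinate in record {self.specimen_id!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def landmark_count(self) -> int:
        return self.coords.shape[0]


@dataclass
class MeristicRecord:
    """Six meristic counts for one specimen.

    NSLL/NSALL/NSULL are lateral-line, above- and under-lateral-line scale
    counts; NRDF/NRPF/NRAF are dorsal-, pectoral- and anal-fin ray counts.
    """

    specimen_id: str
    counts: dict
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in MERISTIC_CHARACTERS if c not in self.counts]
        if missing:
            raise ValueError(f"missing meristic characters: {missing}")
        for name in MERISTIC_CHARACTERS:
            v = self.counts[name]
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            self.counts[name] = int(v)

    def __getitem__(self, name: str) -> int:
        return self.counts[name]


@dataclass
class SeqEntry:
    specimen_id: str
    taxon: str
    residues: str


@dataclass
class SequenceSet:
    """A set of (optionally aligned) sequences for one molecular marker."""

    marker: str
    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.marker not in VALID_MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {VALID_MARKERS}")
        if not self.entries:
            raise ValueError("SequenceSet must be non-empty")

    @property
    def aligned(self) -> bool:
        lengths = {len(e.residues) for e in self.entries}
        return len(lengths) == 1

    @property
    def length(self) -> int:
        if not self.aligned:
            raise ValueError("sequence set is not aligned; rows differ in length")
        return len(self.entries[0].residues)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        if not self.aligned:
            raise ValueError("sequence set is not aligned; rows differ in length")
        return np.array([list(e.residues) for e in self.entries])

    def taxa(self) -> list:
        return [e.taxon for e in self.entries]

    def subset(self, specimen_ids: Sequence[str]) -> "SequenceSet":
        wanted = set(specimen_ids)
        return SequenceSet(self.marker, [e for e in self.entries if e.specimen_id in wanted])


# ---------------------------------------------------------------------------
# TPS landmark files


def read_tps(path) -> list:
    """Parse a TPS landmark file into a list of :class:`TpsRecord`.

    Records appear in file order.  Raises :class:`ParseError`, naming the
    offending line number, when the declared ``LM=`` count does not match
    the number of coordinate lines or a coordinate is non-numeric.
    """
    path = Path(path)
    records: list = []
    lines = path.read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"{path}:{i + 1}: expected 'LM=' line, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: malformed landmark count {line!r}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= n:
                raise ParseError(f"{path}:{i}: expected {k} coordinate lines, found {j}")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{i + 1}: expected {k} coordinate lines, "
                    f"found {j} before {lines[i].strip()!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 1}: non-numeric coordinate {lines[i].strip()!r}") from exc
            i += 1
        specimen_id = f"record{len(records) + 1}"
        scale = None
        image = None
        while i < n:
            tail = lines[i].strip()
            up = tail.upper()
            if up.startswith("ID="):
                specimen_id = tail.split("=", 1)[1].strip()
            elif up.startswith("IMAGE="):
                image = tail.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                try:
                    scale = float(tail.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i + 1}: non-numeric SCALE {tail!r}") from exc
            else:
                break
            i += 1
        records.append(TpsRecord(specimen_id=specimen_id, coords=coords, scale=scale, image=image))
    return records


def write_tps(records: Sequence[TpsRecord], path) -> None:
    """Write records in the same TPS dialect :func:`read_tps` accepts."""
    path = Path(path)
    out = []
    for rec in records:
        out.append(f"LM={rec.landmark_count}")
        for x, y in rec.coords:
            out.append(f"{x:.12g} {y:.12g}")
        if rec.image is not None:
            out.append(f"IMAGE={rec.image}")
        out.append(f"ID={rec.specimen_id}")
        if rec.scale is not None:
            out.append(f"SCALE={rec.scale:.12g}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Meristic CSV


def read_meristic_csv(path) -> list:
    """Read a meristic count table (CSV, header row, case-insensitive names)."""
    path = Path(path)
    df = pd.read_csv(path)
    colmap = {c.strip().upper(): c for c in df.columns}
    missing = [name for name in MERISTIC_CHARACTERS if name not in colmap]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    id_col = colmap.get("SPECIMEN_ID")
    taxon_col = colmap.get("TAXON")
    records = []
    for idx, row in df.iterrows():
        counts = {}
        for name in MERISTIC_CHARACTERS:
            raw = row[colmap[name]]
            try:
                val = float(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: row {idx + 2}: non-numeric {name} value {raw!r}") from exc
            if not val.is_integer():
                raise ParseError(f"{path}: row {idx + 2}: non-integer {name} value {raw!r}")
            counts[name] = int(val)
        specimen_id = str(row[id_col]) if id_col else f"row{idx + 1}"
        taxon = str(row[taxon_col]) if taxon_col and not pd.isna(row[taxon_col]) else None
        records.append(MeristicRecord(specimen_id=specimen_id, counts=counts, taxon=taxon))
    return records


def write_meristic_csv(records: Sequence[MeristicRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"specimen_id": rec.specimen_id, "taxon": rec.taxon or ""}
        row.update(rec.counts)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, marker: str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Residues are upper-cased; characters outside ``{A,C,G,T,N,-}`` raise
    :class:`ParseError` naming the record and 1-based position.
    """
    path = Path(path)
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        if "|" in header:
            specimen_id, taxon = header.split("|", 1)
        else:
            specimen_id, taxon = header, "unknown"
        residues = str(rec.seq).upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in VALID_RESIDUES:
                raise ParseError(
                    f"{path}: record {specimen_id!r}: illegal residue {ch!r} at position {pos}"
                )
        entries.append(SeqEntry(specimen_id=specimen_id, taxon=taxon, residues=residues))
    if not entries:
        raise ParseError(f"{path}: no FASTA records found")
    return SequenceSet(marker=marker, entries=entries)


def write_fasta(seqset: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(e.residues), id=f"{e.specimen_id}|{e.taxon}", description="")
        for e in seqset.entries
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# JSON result records


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
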