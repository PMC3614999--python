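"""SYNTHETIC stand-in haplotype sets emulating the deposited study sequences.

The study's haplotypes are deposited in GenBank and are not redistributed
here; instead this module deterministically constructs synthetic sequence
sets that plant the same reported summary structure, so that the summary
statistics code can be exercised end to end against known truth:

* cyt b: 16 haplotypes x 1131 bp with exactly 248 variable sites (21.9%),
  distributed over the four species;
* RAG1: 5 haplotypes x 840 bp with exactly 24 variable sites (2.8%);
* Cyfun P: 6 haplotypes (2 S. lucumonis, 1 S. squalus, 1 T. muticellus,
  2 R. rubilio) in a 452-column alignment with exactly 3 diagnostic
  substitutions between the two Squalius species (2 transversions, 1
  transition), a 17 bp 3'-terminal deletion private to S. lucumonis,
  99.7% identity between the two S. lucumonis haplotypes, 98.5% between
  the two R. rubilio haplotypes, and genus-diagnostic ungapped band
  lengths (~310 bp T. muticellus, ~410 bp Squalius, 452 bp R. rubilio).

Every sequence is synthetic; none matches any deposited accession.  The
construction is frozen (fixed internal seed) so the sets are versioned
fixtures in code form.
"""

from __future__ import annotations

import numpy as np

from .io import SeqEntry, SequenceSet

_BASES = "ACGT"
_SEED = 60392  # frozen; the stand-ins are fixtures, not simulations

# transitions stay within purines/pyrimidines; transversions cross
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _transversion(code: int) -> int:
    return {0: 3, 1: 2, 2: 1, 3: 0}[code]  # A->T, C->G, G->C, T->A


def _derive(code: int) -> int:
    return (code + 1) % 4


def synthetic_cytb_haplotypes() -> SequenceSet:
    """16 synthetic cyt b haplotypes, 1131 bp, exactly 248 variable sites.

    Haplotype roster: 6 S. lucumonis (Sl), 4 S. squalus (Ss),
    3 T. muticellus (Tm), 3 R. rubilio (Rr).  Variable sites: 60 fixed in
    the Squalius clade, 60 in Tm, 60 in Rr, 30 fixed between Sl and Ss,
    and 38 singletons distributed round-robin so all haplotypes are
    distinct.
    """
    rng = np.random.default_rng(_SEED)
    length = 1131
    ancestor = rng.integers(0, 4, size=length)
    taxa = ["Sl"] * 6 + ["Ss"] * 4 + ["Tm"] * 3 + ["Rr"] * 3
    rows = {t: [i for i, x in enumerate(taxa) if x == t] for t in ("Sl", "Ss", "Tm", "Rr")}
    seqs = np.tile(ancestor, (16, 1))
    positions = rng.choice(length, size=248, replace=False)
    blocks = [
        (positions[0:60], rows["Sl"] + rows["Ss"]),
        (positions[60:120], rows["Tm"]),
        (positions[120:180], rows["Rr"]),
        (positions[180:210], rows["Sl"]),
    ]
    for pos_block, members in blocks:
        for pos in pos_block:
            seqs[members, pos] = _derive(ancestor[pos])
    singles = positions[210:248]
    for j, pos in enumerate(singles):
        seqs[j % 16, pos] = _derive(int(seqs[j % 16, pos]))
    entries = [
        SeqEntry(
            specimen_id=f"SYN-CYTB-{i + 1:02d}",
            taxon=taxa[i],
            residues="".join(_BASES[c] for c in seqs[i]),
        )
        for i in range(16)
    ]
    return SequenceSet(marker="cytb", entries=entries)


def synthetic_rag1_haplotypes() -> SequenceSet:
    """5 synthetic RAG1 haplotypes, 840 bp, exactly 24 variable sites.

    Roster: 2 Sl, 1 Ss, 1 Tm, 1 Rr.  Variable sites: 4 fixed in the
    Squalius clade, 6 in Tm, 6 in Rr, 3 fixed between Sl and Ss, and 5
    singletons (one per haplotype).
    """
    rng = np.random.default_rng(_SEED + 1)
    length = 840
    ancestor = rng.integers(0, 4, size=length)
    taxa = ["Sl", "Sl", "Ss", "Tm", "Rr"]
    seqs = np.tile(ancestor, (5, 1))
    positions = rng.choice(length, size=24, replace=False)
    blocks = [
        (positions[0:4], [0, 1, 2]),   # Squalius clade
        (positions[4:10], [3]),        # Tm
        (positions[10:16], [4]),       # Rr
        (positions[16:19], [0, 1]),    # Sl vs Ss
    ]
    for pos_block, members in blocks:
        for pos in pos_block:
            seqs[members, pos] = _derive(ancestor[pos])
    for j, pos in enumerate(positions[19:24]):
        seqs[j, pos] = _derive(int(seqs[j, pos]))
    entries = [
        SeqEntry(
            specimen_id=f"SYN-RAG1-{i + 1:02d}",
            taxon=taxa[i],
            residues="".join(_BASES[c] for c in seqs[i]),
        )
        for i in range(5)
    ]
    return SequenceSet(marker="rag1", entries=entries)


# Cyfun P alignment geometry (0-based columns of the 452-column alignment)
CYFUNP_LENGTH = 452
TM_GAP = (150, 142)  # band ~310 bp in T. muticellus
SQUALIUS_GAP = (200, 37)  # bands ~415/398 bp in the two Squalius species
SL_TERMINAL_GAP = (435, 17)  # the 17 bp 3'-terminal deletion in S. lucumonis


def synthetic_cyfunp_haplotypes() -> SequenceSet:
    """6 synthetic Cyfun P haplotypes in a 452-column alignment.

    Plants: exactly 3 fixed Sl/Ss substitutions (A->T and C->G
    transversions plus a G->A transition), the 17 bp terminal deletion in
    Sl, 1 difference between the two Sl haplotypes (99.7% identity over
    their 398 shared bases) and 7 between the two Rr haplotypes (98.5%
    over 452).
    """
    rng = np.random.default_rng(_SEED + 2)
    length = CYFUNP_LENGTH
    ancestor = rng.integers(0, 4, size=length)
    taxa = ["Sl", "Sl", "Ss", "Tm", "Rr", "Rr"]
    seqs = np.tile(ancestor, (6, 1))

    def in_open(pos, *gaps):
        return all(not (s <= pos < s + l) for s, l in gaps)

    open_cols = [
        p
        for p in range(length)
        if in_open(p, TM_GAP, SQUALIUS_GAP, SL_TERMINAL_GAP)
    ]
    picks = rng.choice(len(open_cols), size=40, replace=False)
    cols = [open_cols[i] for i in picks]
    # 3 diagnostic Sl/Ss substitutions: Sl carries the derived state
    d1, d2, d3 = cols[0:3]
    seqs[[0, 1], d1] = _transversion(int(ancestor[d1]))
    seqs[[0, 1], d2] = _transversion(int(ancestor[d2]))
    seqs[[0, 1], d3] = _TRANSITION[int(ancestor[d3])]
    # 1 difference between the two Sl haplotypes
    seqs[1, cols[3]] = _derive(int(ancestor[cols[3]]))
    # Tm private substitutions (12) and Rr-shared substitutions (10)
    for pos in cols[4:16]:
        seqs[3, pos] = _derive(int(ancestor[pos]))
    for pos in cols[16:26]:
        seqs[[4, 5], pos] = _derive(int(ancestor[pos]))
    # 7 differences between the two Rr haplotypes
    for pos in cols[26:33]:
        seqs[5, pos] = _derive(int(seqs[5, pos]))

    def gapped(codes, *gaps):
        chars = np.array(list("".join(_BASES[c] for c in codes)))
        for s, l in gaps:
            chars[s : s + l] = "-"
        return "".join(chars)

    residues = [
        gapped(seqs[0], SQUALIUS_GAP, SL_TERMINAL_GAP),
        gapped(seqs[1], SQUALIUS_GAP, SL_TERMINAL_GAP),
        gapped(seqs[2], SQUALIUS_GAP),
        gapped(seqs[3], TM_GAP),
        gapped(seqs[4]),
        gapped(seqs[5]),
    ]
    entries = [
        SeqEntry(specimen_id=f"SYN-CYF-{i + 1:02d}", taxon=taxa[i], residues=residues[i])
        for i in range(6)
    ]
    return SequenceSet(marker="cyfunp", entries=entries)


def synthetic_reference_sets() -> dict:
    """All three stand-in haplotype sets, keyed by marker."""
    return {
        "cytb": synthetic_cytb_haplotypes(),
        "rag1": synthetic_rag1_haplotypes(),
        "cyfunp": synthetic_cyfunp_haplotypes(),
    }
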