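"""Six-frame translation of genomic DNA and peptide-to-genome coordinate mapping.

Homeobox surveys scan *translated* genomic DNA rather than annotated proteins, so
that unannotated loci and pseudogenes are not missed.  This module turns a DNA
sequence into the six frame peptides (three forward, three on the reverse
complement) and maps residue intervals on those peptides back to forward-strand
genomic coordinates.

Conventions
-----------
* Frames are labelled +1, +2, +3 (forward, offsets 0/1/2) and -1, -2, -3
  (reverse complement, offsets 0/1/2 from the 3' end of the forward strand).
* All coordinates are 0-based, half-open.  Conversion to 1-based inclusive
  happens only at GFF3 emission time.
* Stop codons translate to ``'*'`` and are retained in the frame peptide:
  in-frame stops are evidence for pseudogene classification downstream, so
  translation never splits at them.
* Any codon containing ``N`` translates to ``'X'`` (never ``'*'``), so assembly
  gaps cannot masquerade as disabling mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)

_DNA_ALPHABET = frozenset("ACGTN")

__all__ = ["FramePeptide", "FRAMES", "translate_six_frames", "map_peptide_to_genome"]


@dataclass(frozen=True)
class FramePeptide:
    """One reading-frame translation of a genomic sequence.

    ``len(peptide)`` equals ``(source_length - offset) // 3`` where
    ``offset = abs(frame) - 1``; negative frames are translations of the
    reverse complement.
    """

    sequence_id: str
    frame: int
    peptide: str
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1


def _translate(dna: str) -> str:
    """Translate a DNA string codon by codon (standard code, table 1).

    Trailing bases that do not fill a codon are dropped.  Codons containing N
    become 'X'.
    """
    usable = len(dna) - len(dna) % 3
    trimmed = dna[:usable]
    if "N" not in trimmed:
        return str(Seq(trimmed).translate(table=1))
    out = []
    for i in range(0, usable, 3):
        codon = trimmed[i : i + 3]
        out.append("X" if "N" in codon else str(Seq(codon).translate(table=1)))
    return "".join(out)


def translate_six_frames(dna: str, sequence_id: str = "seq") -> list[FramePeptide]:
    """Translate ``dna`` in all six reading frames.

    Parameters
    ----------
    dna:
        Sequence over {A, C, G, T, N}, case-insensitive.

    Returns
    -------
    list of :class:`FramePeptide`, in frame order +1, +2, +3, -1, -2, -3.
    All six frames are returned even when a frame peptide is empty.

    Raises
    ------
    ValueError
        If the sequence contains characters outside the alphabet.
    """
    dna = dna.upper()
    bad = set(dna) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)!r}")
    rc = str(Seq(dna).reverse_complement())
    out = []
    for frame in FRAMES:
        source = dna if frame > 0 else rc
        off = abs(frame) - 1
        out.append(
            FramePeptide(
                sequence_id=sequence_id,
                frame=frame,
                peptide=_translate(source[off:]),
                source_length=len(dna),
            )
        )
    return out


def map_peptide_to_genome(
    sequence_length: int, frame: int, peptide_interval: tuple[int, int]
) -> tuple[tuple[int, int], str]:
    """Map a residue interval on a frame peptide to genomic coordinates.

    For frame +k, residue ``i`` covers bases ``[(k-1) + 3i, (k-1) + 3i + 3)``.
    For frame -k, residue ``i`` covers bases
    ``[L - (k-1) - 3(i+1), L - (k-1) - 3i)`` on the forward strand.

    Returns
    -------
    ``((start, end), strand)`` with a 0-based half-open forward-strand
    interval; strand is ``'+'`` for positive frames and ``'-'`` for negative.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    start, end = peptide_interval
    off = abs(frame) - 1
    n_residues = (sequence_length - off) // 3
    if not (0 <= start < end <= n_residues):
        raise ValueError(
            f"peptide interval [{start}, {end}) out of range for frame {frame} "
            f"(length {n_residues})"
        )
    if frame > 0:
        return (off + 3 * start, off + 3 * end), "+"
    return (sequence_length - off - 3 * end, sequence_length - off - 3 * start), "-"
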