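"""Family-by-species presence/absence matrices of gene content.

The unit of comparison throughout the package is the *gene family*: a family is
scored ``present`` in a species when the species carries at least one locus of
that family whose status is ``gene``.  Pseudogene-only families score
``absent`` — a disabled remnant is treated as a loss of the gene.  Species for
which no survey was performed are ``unknown``, and unknown is never coerced to
absent: partial assemblies must not create spurious loss calls.

CSV encoding uses the field's compact symbols: ``P`` present, ``-`` absent,
``?`` unknown.  ``--`` is accepted on read as absent (it occurs in published
tables, apparently as a typographic variant) and a warning is logged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"
STATES = (PRESENT, ABSENT, UNKNOWN)

_SYMBOL_TO_STATE = {"P": PRESENT, "-": ABSENT, "--": ABSENT, "?": UNKNOWN}
_STATE_TO_SYMBOL = {PRESENT: "P", ABSENT: "-", UNKNOWN: "?"}

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "PresenceMatrix",
    "build_matrix",
    "read_matrix",
    "write_matrix",
]


class PresenceMatrix:
    """Ordered families x ordered species, every cell in {present, absent, unknown}."""

    def __init__(
        self,
        families: Iterable[str],
        species: Iterable[str],
        states: Mapping[tuple[str, str], str],
    ):
        self.families = list(families)
        self.species = list(species)
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        self._states = {}
        for fam in self.families:
            for sp in self.species:
                st = states.get((fam, sp))
                if st not in STATES:
                    raise ValueError(f"cell ({fam}, {sp}) has invalid state {st!r}")
                self._states[(fam, sp)] = st

    def state(self, family: str, species: str) -> str:
        return self._states[(family, species)]

    def row(self, family: str) -> dict[str, str]:
        return {sp: self._states[(family, sp)] for sp in self.species}

    def species_with_state(self, family: str, state: str) -> list[str]:
        return [sp for sp in self.species if self._states[(family, sp)] == state]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self._states[(f, s)] for s in self.species] for f in self.families],
            index=pd.Index(self.families, name="family"),
            columns=self.species,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.families == other.families
            and self.species == other.species
            and self._states == other._states
        )


def build_matrix(
    locus_tables: Mapping[str, list],
    families: Iterable[str],
    species: Iterable[str] | None = None,
) -> PresenceMatrix:
    """Score gene-family presence per species from called locus tables.

    Parameters
    ----------
    locus_tables:
        species label -> list of :class:`homeodyn.loci.Locus` from that
        species' survey.
    families:
        family labels to score (rows).
    species:
        full species list (columns).  Species listed here but missing from
        ``locus_tables`` were not surveyed and get ``unknown`` in every row.
        Defaults to the keys of ``locus_tables``.

    A family is present iff the species has at least one locus of that family
    with status ``gene``; pseudogene-only families are absent.  Loci without a
    family assignment contribute nothing (a warning is logged).
    """
    families = list(families)
    species_list = list(species) if species is not None else sorted(locus_tables)
    states: dict[tuple[str, str], str] = {}
    for sp in species_list:
        if sp not in locus_tables:
            for fam in families:
                states[(fam, sp)] = UNKNOWN
            continue
        genes_by_family: set[str] = set()
        for locus in locus_tables[sp]:
            if locus.family is None or locus.family == "unclassified":
                logger.warning(
                    "locus %s:%d-%d in %s has no family assignment; ignored",
                    locus.sequence_id,
                    locus.start,
                    locus.end,
                    sp,
                )
                continue
            if locus.status == "gene":
                genes_by_family.add(locus.family)
        for fam in families:
            states[(fam, sp)] = PRESENT if fam in genes_by_family else ABSENT
    return PresenceMatrix(families, species_list, states)


def read_matrix(path) -> PresenceMatrix:
    """Read a presence/absence CSV (header = species, first column = family).

    Symbols: ``P`` present, ``-`` absent, ``?`` unknown; ``--`` is accepted as
    absent with a logged warning.  Any other symbol, a ragged row or an empty
    cell is an error naming the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if df.shape[1] < 2:
        raise ValueError("matrix CSV needs a family column plus >=1 species column")
    species = [c.strip() for c in df.columns[1:]]
    families = [str(f).strip() for f in df.iloc[:, 0]]
    states: dict[tuple[str, str], str] = {}
    for fam, (_, rowvals) in zip(families, df.iloc[:, 1:].iterrows()):
        for sp, cell in zip(species, rowvals):
            cell = str(cell).strip()
            if cell == "":
                raise ValueError(f"empty cell at row {fam!r}, column {sp!r}")
            if cell not in _SYMBOL_TO_STATE:
                raise ValueError(
                    f"unknown symbol {cell!r} at row {fam!r}, column {sp!r}"
                )
            if cell == "--":
                logger.warning(
                    "symbol '--' at row %r, column %r read as absent", fam, sp
                )
            states[(fam, sp)] = _SYMBOL_TO_STATE[cell]
    return PresenceMatrix(families, species, states)


def write_matrix(matrix: PresenceMatrix, path) -> None:
    """Write a presence matrix as CSV with symbols P / - / ?."""
    df = matrix.to_frame().replace(_STATE_TO_SYMBOL)
    df.to_csv(path)
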