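"""Packaged fixtures: the published gene-content table, the species tree, and
the synthetic homeodomain reference alignment.

``table2.csv`` encodes, verbatim, the published taxonomic distribution of the
fourteen homeobox gene families that differ between the human and mouse
genomes, over eleven vertebrate species (P = present, - = absent; one cell
uses ``--``, which the reader treats as absent with a warning).

``mammal_tree.nwk`` is the rooted 11-species tree used to polarize those
differences: frog, then chicken, as successive outgroups to the placental
mammals, which split into Supraprimates (primates + rodents) and
Laurasiatheria (cow, pig, horse, dog).

``synthetic_homeodomains.afa`` is a synthetic 60-column reference panel
derived from the Antennapedia homeodomain (see
:func:`homeodyn.synthetic.make_reference_set`); it stands in for a curated
homeodomain alignment so the whole pipeline runs self-contained.
"""

from __future__ import annotations

from importlib import resources

from .dollo import SpeciesTree, parse_tree
from .hmm import HomeodomainAlignment
from .matrix import PresenceMatrix, read_matrix
from .synthetic import ReferenceSet

__all__ = [
    "table2_path",
    "table2_matrix",
    "mammal_tree",
    "homeodomain_alignment",
    "reference_set",
]


def _data(name: str):
    return resources.files("homeodyn").joinpath("data", name)


def table2_path():
    return _data("table2.csv")


def table2_matrix() -> PresenceMatrix:
    """The packaged 14-family x 11-species presence/absence matrix."""
    with resources.as_file(table2_path()) as p:
        return read_matrix(p)


def mammal_tree() -> SpeciesTree:
    """The packaged rooted 11-species tree."""
    return parse_tree(_data("mammal_tree.nwk").read_text().strip())


def homeodomain_alignment() -> HomeodomainAlignment:
    """The synthetic 60-column homeodomain reference alignment."""
    with resources.as_file(_data("synthetic_homeodomains.afa")) as p:
        return HomeodomainAlignment.from_fasta(p)


def reference_set() -> ReferenceSet:
    """The synthetic reference panel with per-family expected homeobox counts."""
    with resources.as_file(_data("synthetic_homeodomains.afa")) as p:
        return ReferenceSet.from_alignment_fasta(p)
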