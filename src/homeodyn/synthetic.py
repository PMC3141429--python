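"""Synthetic genomes, truth annotations, and simulated gene-content histories.

Everything downstream — six-frame translation, profile-HMM scanning, locus
calling, matrix assembly and Dollo inference — is testable against planted
truth produced here, with no genome downloads.

What is emulated
----------------
* Intact homeobox loci: a 60-residue homeodomain reverse-translated with
  uniformly random synonymous codons (standard genetic code) and embedded in
  i.i.d. background DNA at a configurable GC content.
* Pseudogenes: an in-frame stop codon planted inside the homeobox, a 1-bp
  frameshift deletion at a chosen codon, or loss of the second homeobox of a
  double-homeobox (Dux-type) locus.
* Gene structure: double homeoboxes separated by a linker, tandem arrays,
  loci on either strand, and GT...AG-bounded putative introns splitting the
  homeobox at a codon boundary.
* Gene-content evolution: each family gains exactly once on a branch of a
  rooted species tree and is lost independently per branch below the gain —
  the generative counterpart of the Dollo assumption.

The reference homeodomain set is synthetic: families are derived from the
canonical Antennapedia homeodomain by seeded substitutions, giving a
realistic (~70% pairwise identity) but fully self-contained family panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .dollo import SpeciesTree
from .matrix import ABSENT, PRESENT, PresenceMatrix

#: The Antennapedia-class homeodomain, the textbook 60-residue anchor from
#: which synthetic family variants are derived.
ANTP_HOMEODOMAIN = "RKRGRQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"

HOMEODOMAIN_LENGTH = 60
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_LINKER = 300  # bp between the two boxes of a double-homeobox locus

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()

__all__ = [
    "ANTP_HOMEODOMAIN",
    "LocusSpec",
    "TruthRecord",
    "TruthLog",
    "ReferenceSet",
    "make_reference_set",
    "pseudogenize",
    "build_genome",
    "simulate_family_evolution",
    "random_binary_tree",
    "default_fixture",
    "DefaultFixture",
]


@dataclass(frozen=True)
class LocusSpec:
    """Plan for one planted homeobox locus."""

    family_name: str
    homeodomain_peptide: str
    n_homeoboxes: int = 1
    strand: str = "+"
    disruption: str = "none"  # none | stop | frameshift | truncate
    disruption_position: int | None = None  # residue index 0..59
    stop_codon: str | None = None
    intron: int | None = None  # inserted intron length in bp
    intron_codon: int = 30  # codon boundary for the intron

    def __post_init__(self):
        if len(self.homeodomain_peptide) != HOMEODOMAIN_LENGTH:
            raise ValueError("homeodomain peptide must be 60 residues")
        if "*" in self.homeodomain_peptide:
            raise ValueError("homeodomain peptide must not contain a stop symbol")
        if self.n_homeoboxes not in (1, 2):
            raise ValueError("n_homeoboxes must be 1 or 2")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.disruption not in ("none", "stop", "frameshift", "truncate"):
            raise ValueError(f"unknown disruption {self.disruption!r}")
        if self.intron is not None and self.intron < 4:
            raise ValueError("intron must be at least 4 bp (GT...AG)")


@dataclass(frozen=True)
class TruthRecord:
    sequence_id: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    family: str
    status: str  # gene | pseudogene
    disruption: str


@dataclass
class TruthLog:
    """Ground truth emitted alongside generated data."""

    records: list[TruthRecord] = field(default_factory=list)
    simulation_events: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, r in enumerate(self.records, 1):
                fh.write(
                    f"{r.sequence_id}\thomeodyn_truth\thomeobox_locus\t"
                    f"{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                    f"ID=truth{i:04d};family={r.family};status={r.status};"
                    f"disruption={r.disruption}\n"
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "records": [vars(r) for r in self.records],
                    "simulation_events": self.simulation_events,
                },
                fh,
                indent=1,
            )


@dataclass
class ReferenceSet:
    """Labelled homeodomain references; synthetic stand-ins for a curated panel."""

    families: dict[str, str]
    expected_homeoboxes: dict[str, int] = field(default_factory=dict)

    def n_boxes(self, family: str) -> int:
        return self.expected_homeoboxes.get(family, 1)

    def to_alignment_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for fam, pep in self.families.items():
                fh.write(f">{fam} n_homeoboxes={self.n_boxes(fam)}\n{pep}\n")

    @classmethod
    def from_alignment_fasta(cls, path) -> "ReferenceSet":
        families: dict[str, str] = {}
        expected: dict[str, int] = {}
        with open(path) as fh:
            name = None
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    parts = line[1:].split()
                    name = parts[0]
                    families[name] = ""
                    for tag in parts[1:]:
                        if tag.startswith("n_homeoboxes="):
                            n = int(tag.split("=", 1)[1])
                            if n != 1:
                                expected[name] = n
                elif name is not None:
                    families[name] += line
        return cls(families=families, expected_homeoboxes=expected)


def make_reference_set(
    n_families: int = 12,
    n_substitutions: int = 18,
    seed: int = 7,
    double_homeobox_families: Iterable[str] = ("fam03",),
) -> ReferenceSet:
    """Derive a synthetic family panel from the Antennapedia homeodomain.

    Each family is the anchor with ``n_substitutions`` seeded random residue
    changes (~70% identity to the anchor at the default), mimicking the
    divergence between real homeodomain families while staying alignable as a
    gap-free 60-column block.
    """
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    families: dict[str, str] = {}
    for i in range(1, n_families + 1):
        pep = list(ANTP_HOMEODOMAIN)
        positions = rng.choice(HOMEODOMAIN_LENGTH, size=n_substitutions, replace=False)
        for pos in positions:
            choices = [a for a in aas if a != pep[pos]]
            pep[pos] = choices[rng.integers(len(choices))]
        families[f"fam{i:02d}"] = "".join(pep)
    doubles = {f: 2 for f in double_homeobox_families if f in families}
    return ReferenceSet(families=families, expected_homeoboxes=doubles)


def pseudogenize(
    spec: LocusSpec, mode: str, position: int, seed: int = 0
) -> LocusSpec:
    """Mark a locus spec as disrupted.

    ``stop`` replaces one codon with a seeded choice of TAA/TAG/TGA,
    ``frameshift`` deletes 1 bp at the codon start of the given residue, and
    ``truncate`` removes the second homeobox (double-homeobox specs only).
    The DNA-level edit is applied by :func:`build_genome`; the truth status
    becomes pseudogene.
    """
    if mode not in ("stop", "frameshift", "truncate"):
        raise ValueError(f"unknown disruption mode {mode!r}")
    if not (0 <= position < HOMEODOMAIN_LENGTH):
        raise ValueError("position must be a residue index within the homeodomain")
    if mode == "truncate" and spec.n_homeoboxes != 2:
        raise ValueError("truncate requires a double-homeobox spec")
    stop = None
    if mode == "stop":
        rng = np.random.default_rng(seed)
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return replace(
        spec, disruption=mode, disruption_position=position, stop_codon=stop
    )


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codons for each residue (standard code)."""
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in peptide
    )


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs)) if length else ""


def _locus_cassette(
    spec: LocusSpec, rng: np.random.Generator, gc: float, linker: int = DEFAULT_LINKER
) -> str:
    """DNA for one locus, disruptions and intron applied, on the plus strand."""
    box = reverse_translate(spec.homeodomain_peptide, rng)
    if spec.disruption == "stop":
        p = spec.disruption_position
        stop = spec.stop_codon or "TAA"
        box = box[: 3 * p] + stop + box[3 * p + 3 :]
    elif spec.disruption == "frameshift":
        p = spec.disruption_position
        box = box[: 3 * p] + box[3 * p + 1 :]
    if spec.intron is not None:
        cut = 3 * spec.intron_codon
        intron = "GT" + _random_dna(spec.intron - 4, gc, rng) + "AG"
        box = box[:cut] + intron + box[cut:]
    if spec.n_homeoboxes == 2 and spec.disruption != "truncate":
        box2 = reverse_translate(spec.homeodomain_peptide, rng)
        return box + _random_dna(linker, gc, rng) + box2
    return box


def build_genome(
    species: str,
    loci: list[LocusSpec],
    intergenic_length: int = 6000,
    gc_content: float = 0.45,
    seed: int = 0,
    linker: int = DEFAULT_LINKER,
) -> tuple[str, TruthLog]:
    """Embed planted loci in background DNA; return the sequence and its truth.

    The genome is ``bg [cassette bg]*``: each locus cassette (reverse
    translation of its homeodomain, disruptions and introns applied,
    reverse-complemented for minus-strand loci) separated by i.i.d.
    background of the requested GC content.  Truth intervals are exact.
    An empty locus list yields pure background.
    """
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must be within (0, 1)")
    rng = np.random.default_rng(seed)
    seq_id = species
    parts = [_random_dna(intergenic_length, gc_content, rng)]
    pos = intergenic_length
    truth = TruthLog(seed=seed)
    for spec in loci:
        cassette = _locus_cassette(spec, rng, gc_content, linker)
        if spec.strand == "-":
            cassette = _revcomp(cassette)
        parts.append(cassette)
        truth.records.append(
            TruthRecord(
                sequence_id=seq_id,
                start=pos,
                end=pos + len(cassette),
                strand=spec.strand,
                family=spec.family_name,
                status="gene" if spec.disruption == "none" else "pseudogene",
                disruption=spec.disruption,
            )
        )
        pos += len(cassette)
        parts.append(_random_dna(intergenic_length, gc_content, rng))
        pos += intergenic_length
    return "".join(parts), truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def simulate_family_evolution(
    tree: SpeciesTree,
    n_families: int,
    gain_branch_sampler: Callable[[np.random.Generator, list[str]], str] | None = None,
    loss_prob_per_branch: float = 0.1,
    seed: int = 0,
) -> tuple[PresenceMatrix, TruthLog]:
    """Single-gain / independent-loss gene-content evolution on a rooted tree.

    Each family gains exactly once on a sampled branch (uniform over all
    branches unless a sampler is given); on every branch below the gain, loss
    occurs independently with ``loss_prob_per_branch`` and, once lost, stays
    lost.  Leaf states follow deterministically from the event log; the same
    seed reproduces the run byte for byte.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not (0.0 <= loss_prob_per_branch < 1.0):
        raise ValueError("loss_prob_per_branch must be in [0, 1)")
    rng = np.random.default_rng(seed)
    branches = tree.branch_names()
    truth = TruthLog(seed=seed)
    states: dict[tuple[str, str], str] = {}
    families = [f"fam{i:03d}" for i in range(1, n_families + 1)]
    for family in families:
        if gain_branch_sampler is None:
            gain = branches[rng.integers(len(branches))]
        else:
            gain = gain_branch_sampler(rng, branches)
        truth.simulation_events.append((family, gain, "gain"))
        gain_node = tree.branch_child(gain)
        present_leaves: set[str] = set()

        def walk(node, alive: bool) -> None:
            if alive and node is not gain_node:
                # the branch into `node` lies below the gain: loss can strike
                if rng.random() < loss_prob_per_branch:
                    truth.simulation_events.append(
                        (family, tree.branch_name(node), "loss")
                    )
                    alive = False
            if node.is_leaf:
                if alive:
                    present_leaves.add(node.label)
                return
            for child in node.children:
                walk(child, alive)

        walk(gain_node, True)
        for leaf in tree.leaf_labels:
            states[(family, leaf)] = PRESENT if leaf in present_leaves else ABSENT
    matrix = PresenceMatrix(families, tree.leaf_labels, states)
    return matrix, truth


def random_binary_tree(leaf_names: list[str], seed: int = 0) -> str:
    """A random rooted binary Newick topology over the given leaves (for tests)."""
    rng = np.random.default_rng(seed)
    nodes = list(leaf_names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


@dataclass
class DefaultFixture:
    """The package's standard synthetic scenario: 20 loci over 3 species."""

    reference: ReferenceSet
    genomes: dict[str, str]
    truths: dict[str, TruthLog]
    truth_matrix: PresenceMatrix


def default_fixture(seed: int = 2011) -> DefaultFixture:
    """Build the default synthetic survey fixture.

    Twenty planted loci across three species mix intact, stop, frameshift and
    truncation pseudogenes, minus-strand loci, a tandem pair, double-homeobox
    (Dux-type) loci and one intron-split homeobox.  Deterministic in ``seed``.
    """
    refset = make_reference_set(seed=7)
    fam = refset.families

    def spec(name, **kw):
        return LocusSpec(family_name=name, homeodomain_peptide=fam[name], **kw)

    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]

    plans = {
        "sp1": [
            spec("fam01"),
            spec("fam02", strand="-"),
            spec("fam03", n_homeoboxes=2),
            pseudogenize(spec("fam04"), "stop", 30, seed=sub[0]),
            pseudogenize(spec("fam05"), "frameshift", 47),
            spec("fam06", intron=81, intron_codon=30),
            spec("fam07"),
            spec("fam07"),  # tandem array: same family, two separate loci
        ],
        "sp2": [
            spec("fam01"),
            pseudogenize(spec("fam02", strand="-"), "stop", 15, seed=sub[1]),
            pseudogenize(spec("fam03", n_homeoboxes=2), "truncate", 0),
            spec("fam05"),
            spec("fam08", strand="-"),
            pseudogenize(spec("fam06", strand="-"), "frameshift", 30),
        ],
        "sp3": [
            spec("fam01", strand="-"),
            spec("fam02"),
            spec("fam03", n_homeoboxes=2),
            spec("fam04"),
            pseudogenize(spec("fam07"), "stop", 25, seed=sub[2]),
            pseudogenize(spec("fam08", strand="-"), "frameshift", 47),
        ],
    }
    genomes: dict[str, str] = {}
    truths: dict[str, TruthLog] = {}
    states: dict[tuple[str, str], str] = {}
    for i, (species, specs) in enumerate(plans.items()):
        genome, truth = build_genome(species, specs, seed=seed + i)
        genomes[species] = genome
        truths[species] = truth
        genes = {s.family_name for s in specs if s.disruption == "none"}
        for family in fam:
            states[(family, species)] = PRESENT if family in genes else ABSENT
    truth_matrix = PresenceMatrix(list(fam), list(plans), states)
    return DefaultFixture(
        reference=refset, genomes=genomes, truths=truths, truth_matrix=truth_matrix
    )
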