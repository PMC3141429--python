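# Methods

This note documents the models, parameters and design choices behind
`homeodyn`, and what the synthetic benchmarks do and do not demonstrate.

## Six-frame translation and coordinates

Genomic DNA is translated in frames +1, +2, +3 and, on the reverse
complement, −1, −2, −3 (standard genetic code).  Stops translate to `*` and
are kept in the frame peptide: translation never splits at stops, because
stop positions are downstream evidence for pseudogene classification.  Any
codon containing `N` becomes `X`, never `*`, so assembly gaps cannot create
spurious disablement evidence.  All internal coordinates are 0-based
half-open on the forward strand; GFF3 output converts to 1-based inclusive.
For frame +k, residue *i* occupies bases [(k−1)+3i, (k−1)+3i+3); the mirror
formula applies on the reverse strand.  The mapping is exercised by a
round-trip property (translate the mapped interval, recover the peptide
slice) over 1000 random draws.

## Profile HMM

**Architecture.**  Match/insert/delete states in the classic profile layout
(transitions M→M/I/D, I→I/M, D→D/M).  Alignment columns with non-gap
occupancy ≥ `match_occupancy_threshold` (default 0.5) become match states in
order.

**Emissions.**  Background residue frequencies are pooled over the whole
training alignment with +1 smoothing.  Match emissions use
background-proportional pseudocounts,

    e_j(a) = (c_j(a) + 20·pc·bg(a)) / (n_j + 20·pc),    pc = 1.0 by default,

reported as log2-odds against the background.  The background-proportional
form (hmmbuild semantics) matters: with flat Laplace pseudocounts a residue
never observed anywhere in the alignment would score ≈ +4.5 bits at every
state (pseudocount floor 1/32 against a pooled-background floor of ~1/740),
and translated random DNA then produces supra-threshold false hits; with the
proportional form unseen residues score slightly below background and
background genomes are clean.

**Stops and ambiguity.**  `*` emits at −20 bits in match *and* insert
states.  Penalizing inserts too is deliberate: otherwise the Viterbi path
threads through stop-riddled intervening sequence (an inserted intron) at
zero cost and single hits silently span structures that the locus caller
needs to see as split.  `X` emits at 0 bits everywhere (score-neutral).

**Search.**  Local Viterbi in both sequence and model: uniform entry into
any match state (cost −log2 M, folded into the score), free exit, bit-score
output.  The fast implementation (vectorized rows, running-max delete chain)
is checked against an independently written naive dynamic program to 1e−9
bits on ≥200 random model/peptide pairs.  Traceback records which residues
the match states emitted (`matched_peptide`); family identity is computed on
this reconstruction, so insert-state junk (e.g. a crossed intron) never
dilutes identity.

**Reporting.**  Default threshold 15 bits; minimum envelope 12 residues
(helix-sized; a helix-3 frameshift leaves a 13-residue fragment that must
remain reportable).  Iterated best-hit-then-mask yields non-overlapping
hits.  A *fragment rescue* pass then handles the one systematic blind spot:
a homeobox split near one end leaves a far-side fragment (≈ a dozen
residues, ~9–10 bits) below any sensible primary threshold.  For each hit
that stops short of the model ends, the few codons immediately beyond it are
searched in the same-strand frames at a permissive 3-bit threshold,
accepting only fragments whose match states continue where the anchor
stopped (tolerance 2 states) and add new coverage; rescue is skipped when a
nearby hit (within 300 bp, spanning linker- or small-intron-scale gaps)
already provides the continuation.  Rescued hits are flagged.  No E-value
calibration is attempted; scores are plain bits.

## Locus calling and classification

Hits on the same sequence and strand within `merge_window` (default 5 kb —
comfortably joins the ~300-bp-spaced homeobox pair of a double-homeobox
locus while leaving tandem-array neighbours, placed several kb apart,
separate) merge into a locus.  Within a locus, hits group into *homeobox
units*:

* full-length hits (≥ `full_span_states` = 50 of ~60 match states) stand
  alone; `homeobox_count` counts units with full coverage (so a Dux-type
  locus counts 2);
* partial hits in different frames that overlap or nearly abut
  (`frameshift_gap` = 45 bp, tolerating ragged envelope ends) and whose
  match states are continuous (tolerance 8 states) form a **frameshift**
  unit;
* same-frame partial hits separated by a gap with GT…AG boundaries (searched
  within ±9 bp of the envelope ends, again because local alignments end
  raggedly) form a putative **intron** unit, with no frameshift flag;
* same-frame partial hits with a small gap and no splice boundaries form a
  plain split unit — the typical signature of a stop codon that the local
  alignment clipped out of both envelopes.

Classification is rule-based and idempotent.  A locus is a pseudogene iff
any of: an in-frame stop inside a matched homeobox span (plain units are
re-translated over their genomic union so a clipped-out stop is still seen;
frameshift/intron units are checked hit-by-hit since their gaps are not in
frame); a frameshift unit; best unit covering < 50 match states
(truncation); or a family expected to carry two homeoboxes retaining only
one.  The expected-count map comes from the reference set — a
single-genome survey cannot know that a lone intact homeobox is a truncated
remnant of a double-homeobox gene; that judgement requires family knowledge
from other species, which is exactly how such cases are recognised in
practice.  A stop in the last few residues of the domain is reported as
truncation rather than a stop, because the local alignment ends before it; a
known limitation.

Family assignment aligns the unit's reconstructed homeodomain globally
(free end gaps, gap open −5, extend −1) against each labelled 60-residue
reference; identity = identical residues / 60.  The default `min_identity`
of 0.70 (inclusive, 42/60) is set so that the ~68–84% identity range seen
among genuinely assignable divergent loci passes while a 35/60 (~58%) match
— the scale of cross-species divergence that should *not* be auto-assigned —
fails and is reported as "unclassified" with the nearest family recorded.
Ties break alphabetically and are flagged ambiguous.

## Presence/absence and Dollo inference

A family is present in a species iff the species has ≥1 locus of the family
with status gene; pseudogene-only families score absent (a disabled remnant
is a loss of the gene); species without a survey are unknown, and unknown is
never coerced to absent, so partial assemblies cannot fabricate losses.
CSV symbols: `P`, `-`, `?`; `--` is accepted as absent with a logged warning
(it occurs in published tables as an unexplained variant of `-`).

Dollo parsimony assumes each family arose exactly once — the natural model
for homeodomain families, where independent double origin of the same family
is implausible.  The gain is placed on the branch entering the MRCA of the
present species (the unique minimum-loss placement; deeper placements are
enumerated only by the testing oracle), and losses on the stems of the
maximal all-absent subtrees within the gain clade.  Unknown leaves are
excluded from the MRCA and never force losses.  Branches are named
`parent>child` with deterministic internal labels (the two smallest
child-subtree minimum leaves, e.g. `chimpanzee+mouse` for the
primate+rodent ancestor), so event reports are diffable.  A lineage summary
tallies, for a focal pair, the families whose gain or loss branches lie on
the path from the pair's MRCA to each focal leaf.

The packaged tree fixes the laurasiatherian interior as
`((cow,pig),(horse,dog))`; the focal human/mouse tallies are invariant to
that arrangement (asserted by a test that permutes the subtree).  An
exhaustive oracle (every gain placement, forced minimal losses, ≤12 leaves)
confirms inference on ≥200 random instances.  For single-leaf perturbations
the minimal loss count obeys one-sided bounds only: flipping a leaf to
present can lower it by at most 1, and flipping a leaf to absent can raise
it by at most 1 (append a terminal loss to the previous optimum), but the
reverse directions are unbounded — a flip can relocate the gain deeper in
the tree or shatter an all-absent subtree into several.  The test suite
asserts the one-sided bounds.

## Synthetic data: what it emulates, and what it does not

The generator reverse-translates 60-residue homeodomains with uniformly
random synonymous codons and embeds them in i.i.d. background DNA
(default GC 0.45), on either strand.  Disruptions: one codon replaced by a
random stop; a 1-bp deletion at a chosen codon start (frameshift); removal
of the second homeobox of a double-homeobox locus (truncation).  Introns are
GT…AG-bounded random segments inserted at a codon boundary (default 81 bp, a
multiple of 3 so the downstream box stays in the same genomic frame).
Gene-content histories follow the single-gain/per-branch-loss model —
the generative counterpart of the Dollo assumption — with a uniform gain
branch and a per-branch loss probability (default 0.1; the literature gives
no rates, so these are free parameters, not estimates).

The reference panel is synthetic: twelve families derived from the canonical
Antennapedia homeodomain by 18 seeded substitutions each (~70% identity to
the anchor), one family marked double-homeobox.  The packaged
`synthetic_homeodomains.afa` is this panel written as a gap-free 60-column
alignment.

The default fixture plants 20 loci across three species, mixing intact,
stop, frameshift (including at the helix-3 boundary, residue 47), truncated,
minus-strand, tandem, double-homeobox and intron-split cases, with
intergenic spacing (6 kb) larger than the merge window.  End-to-end recovery
on this fixture is exact — every planted locus recalled with interval
(±6 bp), strand, family, status and disruption reason, zero background loci
— across 20 independent seeds.

What passing these tests does **not** show: performance on real genome
assemblies.  Real background DNA is repetitive and compositionally biased
(the i.i.d. null understates false-hit rates near low-complexity or
repeat-derived sequence); real pseudogenes decay by many substitutions, not
single planted lesions; codon usage is biased; heterochromatic repeat arrays
with copy-number variation are out of scope; and genome-scale locus
inventories additionally required manual curation (BLAST/structure checks)
that no threshold rule reproduces.  Presence calls for real species are
therefore consumed from the packaged published table rather than recomputed.

## Numerical and procedural choices

* All randomness flows through `numpy.random.default_rng` seeds; every
  generator and the pipeline are byte-deterministic given the seed.
* Viterbi tie-breaks: among equal-scoring cells the earliest end wins;
  traceback prefers continuation over fresh entry (longest envelope,
  earliest start for identical repeats).
* Identity threshold comparisons use a 1e−9 tolerance so 42/60 meets 0.70
  exactly despite binary floating point.
* Problem sizes in tests and the acceptance script (three ~50-kb synthetic
  genomes, 50–100 background genomes of 6–10 kb, 200-instance property
  sweeps, 8-leaf random trees) were chosen to exercise every code path at
  desk scale with comfortable margins.
* The brute-force Dollo oracle is guarded to ≤12 leaves; it exists for
  verification, not analysis.

## Known limitations

Spliced gene models are not built (introns are flagged, not assembled);
retro- vs unitary-pseudogene status is not distinguished; stops within the
terminal handful of homeodomain residues classify as truncation; E-values
are not computed; family assignment is identity-based and cannot adjudicate
cases that genuinely require synteny or expression evidence — such loci
surface as "unclassified" or rely on the packaged published table.
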