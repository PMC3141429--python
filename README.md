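# homeodyn

Homeobox gene survey and gain/loss dynamics on a mammalian species tree.

Homeobox genes — the large superclass of developmental transcription-factor
genes defined by a ~180-bp homeobox encoding a ~60-residue homeodomain — are
organised into gene families whose presence or absence can differ even
between closely related genomes.  A raw human/mouse difference is ambiguous:
it may be a gain on one lineage or a loss on the other.  The ambiguity is
resolved by outgroups: if relatives such as dog or cow carry the family, it
must have existed in the common ancestor of Supraprimates (primates +
rodents) and Laurasiatheria, so its absence in one lineage is a secondary
loss.  `homeodyn` implements that whole chain of reasoning as a reusable
pipeline, for anyone studying gene-family content evolution who wants the
survey and the polarization logic to be reproducible rather than manual:

1. **six-frame translation** of genomic DNA with exact peptide-to-genome
   coordinate mapping (`homeodyn.sixframe`);
2. **profile-HMM homeodomain scanning** — the model is estimated from an
   aligned homeodomain set (match/insert/delete states, log2-odds emissions)
   and searched with a local Viterbi algorithm reporting bit scores
   (`homeodyn.hmm`);
3. **locus calling** — hits merge into loci; double-homeobox (Dux-type)
   loci are counted, frameshift- and intron-split homeoboxes are stitched,
   and each locus is classified gene vs pseudogene with explicit reasons
   (in-frame stop, frameshift, truncation) and assigned to a family by
   homeodomain identity (`homeodyn.loci`);
4. **presence/absence matrices** over families x species, where a
   pseudogene-only family scores absent and unsurveyed species stay unknown
   (`homeodyn.matrix`);
5. **Dollo parsimony** on a rooted species tree: each family gains exactly
   once, on the branch entering the most recent common ancestor of the
   species that carry it, and loses on the stem of every maximal subtree
   whose surveyed species all lack it; gains and losses are then tallied
   along focal lineages (`homeodyn.dollo`).

A synthetic-genome generator (`homeodyn.synthetic`) plants homeobox loci —
intact genes, stop/frameshift/truncation pseudogenes, minus-strand loci,
tandem pairs, double homeoboxes, intron-split boxes — with exact truth
annotations, and simulates single-gain/multiple-loss family histories on a
tree, so every stage is testable without genome downloads.

Under Dollo parsimony the minimum-loss reconstruction is written

```
gain(f) = branch into MRCA{ s : state[f][s] = present }
loss(f) = { stem(T) : T maximal subtree below gain(f) with all surveyed leaves absent }
```

with unknown states excluded from the MRCA and never forcing a loss.

## Worked example

The package ships a 14-family x 11-species gene-content table (the families
that differ between the human and mouse genomes, scored across primates,
rodents, laurasiatherians, chicken and frog) and the rooted mammal tree.
Polarizing every difference:

```
$ homeodyn table2
human: 1 gains ['Leutx'], 1 losses ['Msx3']
mouse: 4 gains ['Crxos1', 'Gm5585', 'Gm7235', 'Obox'], 8 losses ['Argfx', 'Dprx', 'LOC647589', 'Nanognb', 'Rax2', 'Shox', 'Tprx1', 'Ventx']
```

Reading: along the lineage from the human–mouse ancestor to **human** a
single family was lost (*Msx3*, still present in mouse, rat, pig and horse)
and a single new family arose (*Leutx*, found only in primates).  Along the
lineage to **mouse**, eight families were lost and four arose (the *Obox*
cluster plus three neighbouring rodent-specific families) — a striking
asymmetry in gene loss between the two lineages over the same span of
evolutionary time.

The same logic is available from Python (see `examples/table2_gainloss.py`
for per-family gain and loss branches), and the full survey pipeline runs on
synthetic genomes in `examples/scan_synthetic_genome.py` and
`examples/call_and_classify.py`.  The CLI mirrors the stages:
`homeodyn simulate | translate | scan | call | matrix | gainloss | all | table2`.

## Layout

```
src/homeodyn/        library (sixframe, hmm, loci, matrix, dollo, synthetic,
                     pipeline, cli) + packaged data fixtures
examples/            one short narrative script per capability
tests/               pytest suite, incl. independent oracles
scripts/acceptance.py
docs/methods.md      model, parameter and design documentation
```
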