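"""Call loci from domain hits and classify gene vs pseudogene.

Plants an intact gene, a stop-codon pseudogene and a helix-3 frameshift
pseudogene in one genome, then runs the survey: scan -> merge hits into loci
-> assign families by homeodomain identity -> classify with explicit reasons.
"""

from homeodyn.datasets import homeodomain_alignment, reference_set
from homeodyn.hmm import build_profile
from homeodyn.pipeline import survey_genome
from homeodyn.synthetic import LocusSpec, build_genome, pseudogenize

refs = reference_set()
specs = [
    LocusSpec("fam01", refs.families["fam01"]),
    pseudogenize(LocusSpec("fam02", refs.families["fam02"]), "stop", 30, seed=1),
    pseudogenize(LocusSpec("fam04", refs.families["fam04"]), "frameshift", 47),
]
genome, truth = build_genome("demo", specs, seed=7)
hmm = build_profile(homeodomain_alignment())

loci = survey_genome({"demo": genome}, hmm, refs, species="demo")
for locus in loci:
    print(
        f"{locus.start}-{locus.end} ({locus.strand})  family={locus.family}  "
        f"identity={locus.best_identity:.2f}  {locus.status}  "
        f"reasons={sorted(locus.reasons) or '-'}"
    )

# Expected: the first locus is a clean gene; the second is a pseudogene with
# reason stop_in_homeobox (the planted TAA/TAG/TGA sits inside the matched
# envelope); the third is a pseudogene flagged frameshift — the 1-bp deletion
# splits the homeobox across two reading frames, and the short helix-3
# fragment is recovered by the scanner's rescue pass.
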