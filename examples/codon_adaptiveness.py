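"""Relative adaptiveness of synonymous codons and rare-codon clusters.

Scales the embedded human codon-usage table within each synonymous family
(most frequent codon = 100%), scores a synonymous CTG->CTA change, and
recovers a planted rare-codon cluster from a synthetic coding sequence.
"""

from varstab import codons, synth

usage = codons.load_usage_table()
adapt = codons.relative_adaptiveness(usage)

print("leucine family (percent of CTG):")
for codon in ("CTG", "CTC", "TTG", "CTT", "TTA", "CTA"):
    print(f"  {codon}: {adapt.rounded(codon):>3}")

wt, alt, delta = codons.ssnp_effect("ATGCTG", 2, "CTA", adapt)
print(f"synonymous CTG->CTA: {wt:.0f} -> {alt:.0f} (delta {delta:.1f})")

# a 170-codon CDS with a low-adaptiveness block planted at codons 100-121
sim = synth.gen_cds(n_codons=170, blocks=[(100, 121)], seed=1)
profile = codons.profile_cds(sim.sequence, adapt)
clusters = codons.detect_rare_clusters(profile, window=15, threshold=40.0)
for c in clusters:
    print(f"rare-codon cluster: codons {c.start}-{c.end} "
          f"(mean adaptiveness {c.mean_adaptiveness:.1f}%)")

# A drop from 100 to 18 marks a switch to a rarely used codon; a cluster
# of such codons can slow translation and perturb co-translational folding.
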