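"""Bisulfite-convert simulated clones, call methylation, and render a
lollipop report.

With 99.5% conversion efficiency an 'off' clone retains a cytosine only
through conversion failure, while an 'on' clone keeps most of its
cytosines; the pooled average methylation rate tracks f_on * d_on.
"""

from dldm import bisulfite, sim

locus = sim.SimulatedLocus.from_sequence("amp", "CAAT" * 30)  # 30-cytosine amplicon
params = sim.SimParams(n_alleles=12, f_on=0.25, d_on=0.9, conv_eff=0.995, seed=4)
alleles = sim.assign_epialleles(locus, params)

vectors = []
for i, allele in enumerate(alleles):
    clone = sim.bisulfite_convert(allele, conv_eff=0.995, seed=10 + i)
    pairs = bisulfite.align_clone(locus.sequence, clone)
    vectors.append(bisulfite.call_methylation(pairs, clone_id=allele.allele_id))

print(bisulfite.lollipop_text(vectors))
print()
rate = bisulfite.average_methylation_rate(vectors)
print(f"pooled methylation rate: {rate:.3f} "
      f"(filled rows are 'on' alleles; open rows converted almost fully)")
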