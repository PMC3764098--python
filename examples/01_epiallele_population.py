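"""Simulate a haploid on/off epiallele population and inspect its truth.

A disiRNA-like locus is either unmethylated or densely methylated within
each nucleus; here 15% of alleles are 'on' with 90% per-cytosine density.
"""

from dldm import sim

locus = sim.generate_reference(length=800, gc_fraction=0.5, planted_gatc=[200, 500], seed=1)
params = sim.SimParams(n_alleles=100, f_on=0.15, d_on=0.9, d_off=0.0, seed=2)
alleles = sim.assign_epialleles(locus, params)

table = sim.truth_table(alleles)
print(table.head())
print()
n_on = (table["label"] == "on").sum()
print(f"{n_on}/100 alleles are 'on' (expected ~15); 'on' alleles carry "
      f"~{table.loc[table.label == 'on', 'n_meth'].mean():.0f} of "
      f"{len(locus.cytosine_positions)} cytosines methylated, 'off' alleles "
      f"{table.loc[table.label == 'off', 'n_meth'].mean():.1f}.")
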