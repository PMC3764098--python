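"""Closed-loop MSP: digestion of a simulated population plus qPCR recovers
the methylated-template fraction as a percent.

BfuCI destroys templates with any unmethylated GATC site, so the digested/
input signal ratio — normalized by a GATC-free control pair — measures the
fraction of protected (methylated) templates.
"""

from dldm import qpcr, sim
from dldm.qpcr import DIGESTED_BFUCI, INPUT, QpcrWell

locus = sim.SimulatedLocus.from_sequence("msp_locus", "AAGATCAACCTT")
params = sim.SimParams(n_alleles=400, f_on=0.3, d_on=1.0, seed=5)
alleles = sim.assign_epialleles(locus, params)

frac = len(sim.digest_alleles(alleles, "BfuCI").survivors) / len(alleles)
wells = [
    QpcrWell("region", INPUT, sim.simulate_qpcr(1.0)),
    QpcrWell("region", DIGESTED_BFUCI, sim.simulate_qpcr(frac)),
    QpcrWell("ctrl_gatc_free", INPUT, sim.simulate_qpcr(1.0)),
    QpcrWell("ctrl_gatc_free", DIGESTED_BFUCI, sim.simulate_qpcr(1.0)),
]
res = qpcr.msp_percent(wells, "region", "ctrl_gatc_free")
print(f"BfuCI-surviving fraction: {frac:.3f}")
print(f"MSP percent methylation:  {res.percent_methylation:.1f}%")
print("with noiseless qPCR the percent equals 100 x the surviving fraction exactly")
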