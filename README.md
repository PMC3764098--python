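# dldm

Quantification toolkit for **dynamic on/off DNA methylation at disiRNA
loci** in *Neurospora crassa*-style haploid systems.

At disiRNA loci (gene-rich regions producing Dicer-independent small RNAs),
cytosine methylation is not constitutive: within each haploid nucleus a
locus is either essentially unmethylated or densely methylated across
kilobases. Measuring such an on/off epiallele mixture requires a different
toolbox from ordinary methylation averaging, and this package implements
that toolbox end to end:

- **`dldm.sim`** — a synthetic-data generator for the whole study design:
  haploid allele populations with an "on" fraction *f* and per-cytosine
  densities *d_on*/*d_off*, in-silico bisulfite conversion with realistic
  efficiency (unmethylated C → T with probability *e* ≈ 0.995–0.998, 5mC
  protected), methylation-sensitive GATC digestion (DpnII cuts regardless
  of site methylation; BfuCI only at unmethylated sites), RIP-mutated
  sequence composition, strand-specific sRNA read pileups, and qPCR Cts.
- **`dldm.bisulfite`** — per-clone methylation calling against a reference
  amplicon (C = methylated, T = converted, else ambiguous), conversion-rate
  QC, pooled methylation frequency, lollipop reports, and the two
  restriction-protection clone strategies (post-bisulfite DpnII "cut/noncut"
  typing; pre-bisulfite BfuCI enrichment for methylated alleles).
- **`dldm.ripindex`** — sliding-window RIP index
  (CpA+TpG)/(ApC+GpT) over 500-bp windows every 100 bp, with the 0.7
  threshold separating RIP'd from normal sequence.
- **`dldm.srna`** — strand-specific 100-nt window densities of mapped
  small-RNA reads, rDNA filtering by 5'-end containment, and scaling of
  libraries to a common filtered size.
- **`dldm.qpcr`** — ΔCt arithmetic: MSP percent methylation
  `100 · RQ_region(digested/input) / RQ_control(digested/input)` with a
  GATC-free control pair, and MeDIP/ChIP enrichment `IP/input` normalized
  to an unmethylated reference locus and optionally to a reference sample.
- **`dldm.epialleles`** — the inference core: a clone is called "on" when
  its retained-cytosine count is statistically incompatible with conversion
  failure alone (exact binomial tail test under Binomial(n, 1−e), default
  α = 0.01); the methylated-epiallele fraction `f̂ = n_on/n_total` gets an
  exact Clopper–Pearson 95% interval; and a two-component binomial mixture
  fitted by EM and compared to a single binomial by BIC quantifies the
  bimodality behind the on/off claim.

## Worked example

```python
from dldm import sim, bisulfite, epialleles

locus = sim.SimulatedLocus.from_sequence("amp", "CAAT" * 40)   # 40 cytosines
params = sim.SimParams(n_alleles=200, f_on=0.15, d_on=0.9, conv_eff=0.995, seed=1)
alleles = sim.assign_epialleles(locus, params)
counts = []
for i, a in enumerate(alleles):
    clone = sim.bisulfite_convert(a, 0.995, seed=i)
    vec = bisulfite.call_methylation(bisulfite.align_clone(locus.sequence, clone))
    counts.append((vec.n_methylated, vec.n_methylated + vec.n_converted))

labels, _ = epialleles.classify_on_off(counts, conversion_failure=0.005)
est = epialleles.estimate_fraction(labels)
print(est.n_on, est.n_total, round(est.f_hat, 3),
      round(est.ci_low, 3), round(est.ci_high, 3))
```

prints

```
24 200 0.12 0.078 0.173
```

24 of 200 simulated clones are called "on"; the point estimate 0.12 and
the exact 95% interval [0.078, 0.173] bracket the generating fraction 0.15.
On real clone counts the same estimator gives, for 18 digestible clones out
of 123, `f̂ = 0.146` with 95% CI [0.089, 0.221], and for 0 of 111 an upper
bound of 0.033.

The `examples/` directory holds one short script per capability
(population simulation, bisulfite calling, RIP scanning, sRNA densities,
MSP quantification, on/off inference); each prints its numbers with a line
of interpretation. A thin CLI (`dldm run|bscall|onoff|ripscan|srnadensity|quant`)
wraps the same functions for shell use, and `dldm run --seed N --out DIR`
executes the full seeded demo pipeline with byte-reproducible artifacts.

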