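# Methods

## The on/off epiallele model

The population model behind every simulation and every inference in this
package is a two-component haploid mixture. A locus with `n_c` cytosines is
present in `n` haploid copies (alleles); each allele is independently "on"
with probability `f_on` (one Bernoulli draw per allele — each nucleus
switches independently, so the realized on-count is Binomial, not fixed).
An "on" allele methylates each cytosine independently with density `d_on`;
an "off" allele with `d_off` (default 0, i.e. strictly unmethylated — the
data this formalizes show off clones retaining cytosines only at the level
of incomplete conversion, but `d_off` is exposed should sparse background
methylation be wanted). Methylation state lives in a 0/1 vector aligned to
the reference cytosine positions, never in the sequence alphabet.

Only the top strand is modelled for methylation and bisulfite conversion:
the Sanger-clone readout this emulates sequences one strand per clone.
This is a documented limitation — symmetric CpG methylation and
bottom-strand calls are out of scope.

### Bisulfite conversion

Conversion is a per-cytosine Bernoulli: unmethylated C → T with probability
`conv_eff` (defaults 0.995; the QC range observed for complete conversions
is 0.995–0.998), 5mC → T with probability `mC_conv` (default 0). Output
length equals reference length — uracil is represented as T, mirroring the
post-PCR sequence — so clone/reference alignment is purely positional and
indel-containing clones are rejected rather than gap-aligned. The
complement of the measured conversion rate is exactly the null rate the
on/off classifier uses.

### Methylation-sensitive digestion

Both isoschizomers recognize GATC; both digest unmethylated sites, and only
DpnII cuts when the site cytosine is methylated. Hence DpnII cleaves any
allele with ≥1 GATC site, and BfuCI cleaves an allele iff it has ≥1 GATC
site whose (top-strand, offset-3) C is unmethylated. These are the
operational semantics of the assay being modelled, applied as stated rather
than as a full vendor methylation-sensitivity table (Dam methylation of the
A, hemimethylation, and bottom-strand C states are not modelled). A locus
without GATC sites leaves all alleles intact with a warning.

## Clone calling and rates

At each reference cytosine: clone C = methylated, clone T = converted, any
other base = ambiguous. Ambiguous calls (sequencing artifacts, not
conversion information) are excluded from both numerator and denominator of
every rate. Conversion rate is pooled converted/(converted+methylated)
over control clones; average methylation is pooled 5mC over assessable
cytosines, which makes it invariant to clone ordering and to
splitting/merging weighted by cytosine counts. CpG/CHG/CHH context is
annotated per call for reporting but drives no classification rule, since
the on/off pattern involves both symmetric and non-symmetric sites.

Strategy 1 (post-bisulfite typing): a clone is "cut" iff ≥1 reference GATC
site reads exactly GATC (site C retained ⇒ the PCR product is DpnII
digestible). One intact site suffices because digestion at any site
destroys the full-length band; how partially retained multi-site clones
were scored on a gel is not specified anywhere, so the ≥1-site rule is this
package's declared choice. Strategy 2 (pre-bisulfite enrichment) simply
returns the BfuCI-surviving subpopulation.

## RIP index

RIP index = (CpA+TpG)/(ApC+GpT) over overlapping dinucleotides in 500-bp
windows every 100 bp; windows with index < 0.7 are classified RIP'd.
Numerical conventions: an index exactly at threshold is "normal" (RIP'd
DNA lies strictly below the line); trailing partial windows are dropped
rather than rescaled, keeping indices comparable at fixed window size;
dinucleotides containing a non-ACGT base are skipped entirely; zero-
denominator windows carry NaN, are excluded from means/sds and counted
separately, and are never reported as 0.

The index is exactly invariant under reverse complementation (RC maps
CpA↔TpG and ApC↔GpT), so "strandedness" manifests positionally: scanning
the opposite strand mirrors the window profile along the sequence. The
scanner therefore operates on the given top strand only. The RIP simulator
mutates top-strand CpA (C→T) and top-strand TpG (G→A, the bottom-strand
CpA event) with the same rate, reading contexts from the unmutated
sequence; this drives the numerator toward 0 monotonically in the mutation
rate. Under iid equal base composition the numerator and denominator have
equal expectations, so unmutated windows concentrate near index 1
(empirically sd ≈ 0.13 at 500 bp), comfortably above the 0.7 line.

## sRNA window densities

Reads are assigned to non-overlapping 100-nt windows by their 5'-end
position (start on the plus strand, start+length−1 on minus): unambiguous
for 20–25-nt reads and exactly mass-conserving per strand. rDNA filtering
removes a read iff its 5' end lies in an rDNA interval, strand-agnostic,
because ribosomal degradation products map to both strands. Library
scaling divides a common target size (default: the smallest filtered
library, so factors ≤ 1) by each filtered total; scaled density = raw ×
factor with raw counts retained, and factors compose multiplicatively.
Collapsed multiplicities are taken at face value; multimapper weighting is
out of scope.

## qPCR arithmetic

All quantities follow RQ(a vs b) = E^(Ct_b − Ct_a) with amplification
efficiency E defaulting to 2.0 (perfect doubling; per-assay configurable
since measured efficiencies are rarely reported for these assays).
Technical replicates are averaged on the Ct scale — a geometric mean on the
quantity scale — before any ratio is formed; whether replicate Cts or
replicate ratios were historically averaged is unstated, so the Ct-scale
convention is this package's declared, testable choice. MSP percent =
100 × RQ_region(digested vs input) / RQ_control(digested vs input) with a
GATC-free control pair; values marginally above 100 (full protection plus
Ct noise) are clamped to 100 with a logged flag rather than erroring.
Enrichment = IP/input normalized by the same ratio at an unmethylated
reference locus (set to 1), with an optional second normalization dividing
every sample's per-region value by a reference sample's. The Ct simulator
uses Ct = reference_ct − log(q)/log(E) + Gaussian noise with reference_ct
= 20 cycles, an arbitrary plumbing constant that cancels in every ratio.

## On/off inference

A clone's retained-C count under the "off" null is
Binomial(n_cytosines, conversion_failure); the clone is "on" when the
exact upper tail P(X ≥ k) < α (default α = 0.01, conversion_failure =
1 − measured conversion rate). At n = 40 and failure 0.005 this calls "on"
from 3 retained cytosines — off clones at realistic conversion efficiency
essentially never reach it, while dense "on" clones (d_on ≈ 0.9) are tens
of standard deviations away, so classification is near-perfect under the
study conditions and the fraction estimate inherits plain binomial
behaviour. The fraction gets an exact Clopper–Pearson interval (beta
quantiles), conservative by construction (coverage ≥ 95%).

The mixture assessment fits `w·Binom(n_i, p_on) + (1−w)·Binom(n_i, p_off)`
by EM: 5 random restarts plus one quantile-based start (component rates
initialized at the means of the lower/upper halves of per-clone rates),
tolerance 1e−8 on the log-likelihood, max 500 iterations, probabilities
clipped to [1e−9, 1−1e−9], ties broken by best log-likelihood then
earliest start. The log-likelihood ascent property is asserted on every
run. Model choice is BIC against a single binomial (3 vs 1 free
parameters); all-identical counts simply prefer one component. Components
are reported in canonical order p_off ≤ p_on.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analyses assume:
binomial on/off allele mixtures, per-cytosine Bernoulli methylation and
conversion, multinomial read placement over strand-specific window
profiles with a controlled rDNA mass fraction, and exponential qPCR
amplification. It deliberately omits PCR amplification bias, chimeras,
sequencing-error models beyond substitutions at calling (handled as
"ambiguous"), cloning bias toward shorter fragments, diploid genomes, and
spatial correlation of methylation along an amplicon (each cytosine is
independent, whereas real dense methylation is spatially contiguous).
Passing tests therefore demonstrate the correctness of the quantification
machinery under the stated model, not robustness to these real-data
artifacts.

## Problem sizes and defaults

Simulated checks use the study-scale conditions: clone pools of 200 clones
× 40 cytosines at f_on = 0.15, d_on = 0.9, conv_eff = 0.995 for fraction
recovery (500 seeded replicates for interval coverage); 1,000 clones for
the exact bisulfite round trip; 200-allele pools for exhaustive digestion
oracles; 100-kb iid sequence for RIP-scan summaries; three libraries of
4–9k reads with 10% rDNA mass for scaling checks. The demo pipeline uses a
4-kb locus with three planted GATC sites and 200 alleles. All randomness
flows from explicit seeds; identical configuration and seed give
byte-identical artifacts (outputs contain no timestamps; the run manifest
records package version, parameters and a parameter hash).

## Known limitations

Top-strand-only calls; no gapped alignment (indel clones are rejected, not
healed); enzyme semantics limited to the two-rule model above; no
standard-curve qPCR calibration or absolute copy number; no multimapper
weighting or size-class analytics beyond window densities; the on/off
boundary is a declared statistical formalization — no numeric per-clone
cutoff exists in the assay itself.
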