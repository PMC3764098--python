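"""End-to-end demo pipeline: simulate -> call -> infer -> scan -> quantify.

One seeded configuration drives every stage; all artifacts are plain text
(FASTA/BED/bedGraph/TSV/JSON/YAML), contain no timestamps, and are
byte-identical across runs with the same configuration and seed. Every
random operation receives a sub-seed derived deterministically from the
configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bisulfite, epialleles, io, qpcr, ripindex, sim, srna

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of the demo pipeline; round-trips losslessly via YAML."""

    seed: int = 0
    # locus / population
    locus_length: int = 4000
    gc_fraction: float = 0.5
    planted_gatc: list[int] = field(default_factory=lambda: [500, 1500, 2500])
    n_alleles: int = 200
    f_on: float = 0.15
    d_on: float = 0.9
    d_off: float = 0.0
    conv_eff: float = 0.995
    mC_conv: float = 0.0
    # RIP companion region
    rip_p_mut: float = 1.0
    rip_interval: list[int] = field(default_factory=lambda: [1000, 2000])
    # inference
    alpha: float = 0.01
    # RIP scan
    rip_window: int = 500
    rip_step: int = 100
    rip_threshold: float = 0.7
    # sRNA
    srna_window: int = 100
    srna_reads_per_library: list[int] = field(default_factory=lambda: [6000, 9000])
    srna_read_length: int = 22
    srna_rdna_fraction: float = 0.1
    # qPCR
    efficiency: float = 2.0
    ct_noise_sd: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sub_seeds(seed: int, n: int) -> list[int]:
    # stable per-stage seeds, kept below 2**31
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage as configured and return the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 8)

    # --- simulate -----------------------------------------------------
    logger.info("[simulate] reference + epiallele population")
    locus = sim.generate_reference(
        config.locus_length,
        config.gc_fraction,
        config.planted_gatc,
        seed=seeds[0],
        name="disi_sim",
    )
    ripd_locus = sim.apply_rip(
        locus, tuple(config.rip_interval), config.rip_p_mut, seed=seeds[1]
    )
    ripd_locus = sim.SimulatedLocus.from_sequence("disi_sim_ripd", ripd_locus.sequence)
    params = sim.SimParams(
        n_alleles=config.n_alleles,
        f_on=config.f_on,
        d_on=config.d_on,
        d_off=config.d_off,
        conv_eff=config.conv_eff,
        mC_conv=config.mC_conv,
        seed=seeds[2],
    )
    alleles = sim.assign_epialleles(locus, params)
    clone_seqs = {
        a.allele_id: sim.bisulfite_convert(
            a, params.conv_eff, params.mC_conv, seed=seeds[3] + i
        )
        for i, a in enumerate(alleles)
    }
    io.write_fasta(
        {"disi_sim": locus.sequence, "disi_sim_ripd": ripd_locus.sequence},
        outdir / "reference.fasta",
    )
    io.write_fasta(clone_seqs, outdir / "clones.fasta")
    io.write_bed(
        [("disi_sim", g, g + 4, "GATC") for g in locus.gatc_sites],
        outdir / "gatc_sites.bed",
    )
    rdna = [("disi_sim", 0, 200, "rDNA")]
    io.write_bed(rdna, outdir / "rdna.bed")
    io.write_bed(
        [
            ("disi_sim", 0, config.locus_length, "disi_sim"),
            ("disi_sim_ripd", *config.rip_interval, "rip_region"),
        ],
        outdir / "loci.bed",
    )
    sim.truth_table(alleles).to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # --- bisulfite calling --------------------------------------------
    logger.info("[bscall] per-clone methylation calls")
    vectors = []
    for clone_id in sorted(clone_seqs):
        pairs = bisulfite.align_clone(locus.sequence, clone_seqs[clone_id])
        vectors.append(bisulfite.call_methylation(pairs, clone_id=clone_id))
    summaries = [
        bisulfite.summarize_clone(v, clone_seqs[v.clone_id], locus.gatc_sites)
        for v in vectors
    ]
    pd.DataFrame(
        {
            "clone_id": [s.clone_id for s in summaries],
            "n_cytosines": [s.n_cytosines for s in summaries],
            "n_methylated": [s.n_methylated for s in summaries],
            "methylation_fraction": [round(s.methylation_fraction, 6) for s in summaries],
            "strategy1_class": [s.strategy1_class for s in summaries],
        }
    ).to_csv(outdir / "clone_summary.tsv", sep="\t", index=False)
    (outdir / "lollipop.txt").write_text(bisulfite.lollipop_text(vectors) + "\n")

    # --- on/off inference ---------------------------------------------
    logger.info("[onoff] epiallele fraction and mixture fit")
    counts = [(v.n_methylated, v.n_methylated + v.n_converted) for v in vectors]
    labels, _ = epialleles.classify_on_off(
        counts, conversion_failure=1 - config.conv_eff, alpha=config.alpha
    )
    est = epialleles.estimate_fraction(labels)
    pd.DataFrame(
        [
            {
                "n_on": est.n_on,
                "n_total": est.n_total,
                "f_hat": round(est.f_hat, 6),
                "ci_low": round(est.ci_low, 6),
                "ci_high": round(est.ci_high, 6),
            }
        ]
    ).to_csv(outdir / "onoff_estimate.tsv", sep="\t", index=False)
    fit = epialleles.fit_binomial_mixture(counts, seed=seeds[4])
    (outdir / "mixture_fit.json").write_text(
        json.dumps(
            {
                "weight_on": round(fit.weight_on, 6),
                "p_off": round(fit.p_off, 6),
                "p_on": round(fit.p_on, 6),
                "bic_1comp": round(fit.bic_1comp, 4),
                "bic_2comp": round(fit.bic_2comp, 4),
                "prefers_two": fit.prefers_two,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    # --- RIP scan -------------------------------------------------------
    logger.info("[ripscan] RIP-index scan")
    bedgraph_rows = []
    locus_rows = []
    for name, seq in (("disi_sim", locus.sequence), ("disi_sim_ripd", ripd_locus.sequence)):
        result = ripindex.scan(seq, config.rip_window, config.rip_step, chrom=name)
        bedgraph_rows.extend(
            (w.chrom, w.start, w.end, w.index) for w in result.windows if w.defined
        )
        stats_all = ripindex.locus_stats(result, (0, len(seq)))
        locus_rows.append({"locus": name, **{k: v for k, v in stats_all.items()}})
        if name == "disi_sim_ripd":
            io.write_bed(
                ripindex.merge_ripd_segments(result, config.rip_threshold),
                outdir / "ripd_segments.bed",
            )
    io.write_bedgraph(bedgraph_rows, outdir / "rip_index.bedgraph")
    pd.DataFrame(locus_rows).to_csv(
        outdir / "rip_locus_stats.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- sRNA densities -------------------------------------------------
    logger.info("[srnadensity] strand-specific window densities")
    n_windows = config.locus_length // config.srna_window
    peak_plus, peak_minus = n_windows // 3, (2 * n_windows) // 3
    profile_plus = np.ones(n_windows)
    profile_plus[peak_plus] = 50.0
    profile_minus = np.ones(n_windows)
    profile_minus[peak_minus] = 50.0
    totals = {}
    tracks_per_lib = {}
    for i, n_reads in enumerate(config.srna_reads_per_library):
        label = f"lib{i + 1}"
        reads = sim.simulate_reads(
            locus,
            {"+": profile_plus, "-": profile_minus},
            n_reads=n_reads,
            read_length=config.srna_read_length,
            rdna_intervals=rdna,
            rdna_fraction=config.srna_rdna_fraction,
            seed=seeds[5] + i,
            window=config.srna_window,
        )
        io.write_reads_tsv(reads, outdir / f"reads_{label}.tsv")
        kept, removed = srna.filter_rdna(reads, rdna)
        totals[label] = sum(r.count for r in kept)
        tracks_per_lib[label] = srna.window_counts(
            kept, config.srna_window, library_label=label
        )
    factors = srna.compute_scaling(totals)
    for label, tracks in tracks_per_lib.items():
        for (chrom, strand), track in sorted(tracks.items()):
            scaled = srna.normalize(track, factors[label])
            tag = "plus" if strand == "+" else "minus"
            io.write_bedgraph(
                io.track_to_bedgraph_rows(scaled),
                outdir / f"srna_{label}_{tag}.bedgraph",
            )
    pd.DataFrame(
        [
            {"library": lab, "filtered_total": totals[lab], "factor": round(factors[lab], 6)}
            for lab in sorted(totals)
        ]
    ).to_csv(outdir / "srna_scaling.tsv", sep="\t", index=False)

    # --- quantification --------------------------------------------------
    logger.info("[quant] closed-loop MSP percent")
    survived = len(sim.digest_alleles(alleles, "BfuCI").survivors)
    frac = survived / len(alleles) if alleles else 0.0
    wells = []
    for region, q_dig in (("disi_sim", max(frac, 1e-12)), ("control_113_114", 1.0)):
        for condition, q in ((qpcr.INPUT, 1.0), (qpcr.DIGESTED_BFUCI, q_dig)):
            ct = sim.simulate_qpcr(
                q, config.efficiency, config.ct_noise_sd, seed=seeds[6]
            )
            wells.append(
                qpcr.QpcrWell(
                    target_region=region, condition=condition, ct=ct,
                    efficiency=config.efficiency,
                )
            )
    msp = qpcr.msp_percent(
        wells, "disi_sim", "control_113_114", efficiency=config.efficiency
    )
    pd.DataFrame(
        [
            {
                "region": msp.region,
                "percent_methylation": round(msp.percent_methylation, 6),
                "control_pair": msp.control_pair,
                "clamped": msp.clamped,
                "bfuci_surviving_fraction": round(frac, 6),
            }
        ]
    ).to_csv(outdir / "msp.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    config.to_yaml(outdir / "config.yaml")
    io.write_manifest(dataclasses.asdict(config), outdir / "manifest.yaml")
    return outdir
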