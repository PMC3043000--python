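#!/usr/bin/env python
"""Simulate the synthetic study: a 1-Mb genome with 100 planted E-box sites,
two circadian ChIP libraries plus one input (10^5 tags per library and
timepoint, ZT2-ZT22), and write genome, tags and ground truth under
results/analysis/simulation/.

The planted design mirrors the study conditions: binding phases drawn
around ZT6, log-uniform strengths spanning one order of magnitude, tandem
E1-E2 elements with 6-7 bp spacers in about a third of the sites, and a
truncated-Normal(100, 25) fragment-offset kernel.
"""

import sys
from pathlib import Path

import numpy as np

from circabind import synth, tags
from circabind.pipeline import PipelineConfig, sample_site_specs, _write_fasta

OUT = Path("results/analysis/simulation")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    rng = np.random.default_rng(seed)
    genome = synth.generate_genome(cfg.genome_length, cfg.gc_fraction, rng)
    specs = sample_site_specs(cfg, rng)
    genome, truth = synth.plant_sites(
        genome, specs, kernel_mu=cfg.kernel_mu, kernel_sd=cfg.kernel_sd,
        background_rate=cfg.background_rate,
    )
    chip, inp = synth.simulate_chip_tags(truth, cfg.depth, rng)

    _write_fasta(OUT / "genome.fa", truth.chrom, genome)
    truth.to_frame().to_csv(OUT / "truth_sites.tsv", sep="\t", index=False)
    tags.write_bed6(chip, OUT / "chip_tags.bed")
    tags.write_bed6(inp, OUT / "input_tags.bed")

    by_class = truth.to_frame()["site_class"].value_counts()
    print(f"genome: {cfg.genome_length:,} bp, GC {cfg.gc_fraction:.2f}")
    print(f"planted sites: {len(specs)} ({dict(by_class)})")
    print(f"chip tags: {len(chip):,} ({cfg.depth:,} per library x timepoint)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
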