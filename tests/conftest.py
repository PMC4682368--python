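"""Shared fixtures: handcrafted micro-genomes and seeded simulated
datasets (generated once per session; every recovery test asserts against
the generator's planted truth)."""

from __future__ import annotations

import numpy as np
import pytest

from methsuite.formats import GenomeSequence
from methsuite.simulate import (SimulationConfig, plant_snps,
                                simulate_alignments, simulate_genome,
                                simulate_methylome)


def make_genome(**seqs: str) -> dict[str, GenomeSequence]:
    return {name: GenomeSequence(name, seq.upper())
            for name, seq in seqs.items()}


def run_sim(config: SimulationConfig):
    """Genome + methylome + snps + alignments from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    genome, genes, tfbs = simulate_genome(config, rng)
    if config.depth_mean > 0:
        records, met_truth = simulate_methylome(config, genome, genes, tfbs,
                                                rng)
    else:  # alignment-only scenarios skip the methylome draw
        records, met_truth = [], None
    snps = plant_snps(config, genome, rng)
    alignments, aln_truth = simulate_alignments(config, genome, snps, rng)
    return {"config": config, "genome": genome, "genes": genes, "tfbs": tfbs,
            "records": records, "met_truth": met_truth, "snps": snps,
            "alignments": alignments, "aln_truth": aln_truth}


@pytest.fixture(scope="session")
def met_sim():
    """Flat methylome, >=10k sites per context, planted levels
    CG 0.8 / CHG 0.3 / CHH 0.1, Poisson(10) depth."""
    cfg = SimulationConfig(seed=11, chrom_lengths={"chr1": 200_000},
                           n_genes=0, n_tfbs=0, aln_depth_mean=0)
    return run_sim(cfg)


@pytest.fixture(scope="session")
def elements_sim():
    """Gene-bearing methylome with planted promoter hypomethylation
    (promoter CG 0.2 vs gene-body CG 0.8)."""
    cfg = SimulationConfig(seed=23, chrom_lengths={"chr1": 300_000},
                           n_genes=20, n_tfbs=0,
                           promoter_levels={"CG": 0.2}, aln_depth_mean=0)
    return run_sim(cfg)


@pytest.fixture(scope="session")
def tfbs_sim():
    """Intergenic TFBS set with a planted methylation dip (0.1 at the
    anchor against a 0.7 CG background, half-width 90)."""
    cfg = SimulationConfig(seed=31, chrom_lengths={"chr1": 300_000},
                           n_genes=0, n_tfbs=40,
                           levels={"CG": 0.7, "CHG": 0.3, "CHH": 0.1},
                           dip_width=90, dip_level=0.1, aln_depth_mean=0)
    return run_sim(cfg)


@pytest.fixture(scope="session")
def snp_sim():
    """100 homozygous + 50 heterozygous SNPs at A/T reference positions,
    depth 30, conversion 0.99, error-free reads."""
    cfg = SimulationConfig(seed=41, chrom_lengths={"chr1": 150_000},
                           n_genes=0, n_tfbs=0, depth_mean=0,
                           n_hom_snps=100, n_het_snps=50,
                           aln_depth_mean=30, conversion=0.99)
    return run_sim(cfg)


@pytest.fixture(scope="session")
def cnv_sim():
    """1 Mb genome, depth 20, with a 2x gain over 10 bins and a 0.5x loss
    over 8 bins (10 kb bins)."""
    cfg = SimulationConfig(
        seed=3, chrom_lengths={"chr1": 1_000_000}, n_genes=0, n_tfbs=0,
        depth_mean=0, aln_depth_mean=20,
        cnv_segments=(("chr1", 300_001, 400_000, 2.0),
                      ("chr1", 700_001, 780_000, 0.5)))
    return run_sim(cfg)
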