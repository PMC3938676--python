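"""Shared fixtures: small synthetic GBS runs carried through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from gbstag import discovery, production, simdata, tagcounts, tbt as tbt_mod, topm as topm_mod
from gbstag.seqcore import load_enzyme, parse_barcode_key


@dataclass
class PipelineRun:
    cfg: simdata.SimConfig
    truth: simdata.TruthSet
    fastq: object
    key: object
    enzyme: object
    master: tagcounts.MasterTagList
    topm: topm_mod.TOPM
    tbt: tbt_mod.TBT
    tbt_report: object
    paralog_pairs: list | None = None

    @property
    def merged_locus_keys(self) -> set:
        out = set()
        for a, _b in self.paralog_pairs or []:
            la = self.truth.loci[a]
            out.add((la.chrom, la.strand, la.cut_pos))
        return out


def _run_pipeline(cfg, tmp, paralog_pairs_n=0, sam_seed=99) -> PipelineRun:
    truth = simdata.generate_reference(cfg)
    simdata.simulate_population(cfg, truth)
    fastq = tmp / "reads.fastq"
    simdata.simulate_gbs_fastq(cfg, truth, fastq)
    key_path = tmp / "key.tsv"
    simdata.write_key_file(truth, key_path)
    key = parse_barcode_key(key_path)
    enzyme = cfg.enzyme_model
    table, _rep = tagcounts.count_tags(fastq, key, enzyme, cfg.flowcell, cfg.lane)
    master = tagcounts.merge_tag_counts([table], min_count=5)
    pairs = None
    if paralog_pairs_n:
        pairs = simdata.paralog_pair_candidates(
            truth, paralog_pairs_n, np.random.default_rng(sam_seed)
        )
    sam = tmp / "aln.sam"
    simdata.write_truth_sam(master, truth, sam, paralog_pairs=pairs)
    topm = topm_mod.import_sam(sam, master)
    matrix, report = tbt_mod.build_tbt([(fastq, cfg.flowcell, cfg.lane)], key, master, enzyme)
    return PipelineRun(cfg, truth, fastq, key, enzyme, master, topm, matrix, report, pairs)


@pytest.fixture(scope="session")
def apeki():
    return load_enzyme("ApeKI")


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory) -> PipelineRun:
    """Error-free, deep (10x), fully inbred population: genotype truth is
    exactly recoverable, so end-to-end identities can be asserted."""
    cfg = simdata.SimConfig(
        seed=7, ref_length=200_000, site_spacing=800, n_taxa=48,
        inbred_fraction=1.0, selfing_generations=20, n_snps=100,
        mean_depth=10.0, error_rate=0.0,
    )
    return _run_pipeline(cfg, tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def clean_discovery(clean_run):
    prod_topm, report = discovery.run_discovery(
        clean_run.topm, clean_run.tbt, pedigree=clean_run.truth.pedigree
    )
    return prod_topm, report


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> PipelineRun:
    """1% per-base sequencing error plus six paralog-merged locus pairs:
    the regime the population-genetic filters exist for."""
    cfg = simdata.SimConfig(
        seed=11, ref_length=200_000, site_spacing=800, n_taxa=48,
        inbred_fraction=0.9, selfing_generations=6, n_snps=120,
        mean_depth=6.0, error_rate=0.01,
    )
    return _run_pipeline(cfg, tmp_path_factory.mktemp("noisy"), paralog_pairs_n=6)


@pytest.fixture(scope="session")
def noisy_run_low(tmp_path_factory) -> PipelineRun:
    """Same regime as noisy_run but at 0.1% per-base error."""
    cfg = simdata.SimConfig(
        seed=13, ref_length=200_000, site_spacing=800, n_taxa=48,
        inbred_fraction=0.9, selfing_generations=6, n_snps=120,
        mean_depth=6.0, error_rate=0.001,
    )
    return _run_pipeline(cfg, tmp_path_factory.mktemp("noisy_low"), paralog_pairs_n=6)


@pytest.fixture(scope="session")
def ril_population():
    """Truth genotypes for eight 30-line biparental RIL families."""
    cfg = simdata.SimConfig(
        seed=3, ref_length=150_000, site_spacing=800, n_taxa=240,
        n_families=8, family_size=30, selfing_generations=6,
        n_snps=200, mean_depth=2.0,
    )
    truth = simdata.generate_reference(cfg)
    simdata.simulate_population(cfg, truth)
    return truth


def make_genotype_table_from_truth(truth, eps: float = 0.0, seed: int = 17):
    """Direct truth -> GenotypeTable conversion with optional injected
    per-call error (each call replaced by one of the other two genotypes
    with probability eps)."""
    from gbstag.discovery import HET, HOM_MAJOR, HOM_MINOR
    from gbstag.production import GenotypeTable, Site

    rng = np.random.default_rng(seed)
    calls = np.where(
        truth.genotypes == simdata.G_HOM_REF, HOM_MAJOR,
        np.where(truth.genotypes == simdata.G_HOM_ALT, HOM_MINOR, HET),
    ).astype(np.int8)
    if eps > 0:
        err = rng.random(calls.shape) < eps
        bump = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + bump) % 3, calls).astype(np.int8)
    sites = [Site(s.chrom, s.pos, (s.ref_allele, s.alt_allele)) for s in truth.snps]
    return GenotypeTable(list(truth.taxa), sites, calls)
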