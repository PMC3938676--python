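"""Synthetic reference, population and read generation with truth tables."""

import re

import numpy as np
import pytest

from gbstag.seqcore import LaneClassifier, ReadStatus, iter_fastq, revcomp
from gbstag.simdata import (
    G_HET,
    SimConfig,
    generate_reference,
    paralog_pair_candidates,
    simulate_gbs_fastq,
    simulate_population,
    write_key_file,
    write_truth_sam,
)
from gbstag.seqcore import parse_barcode_key
from gbstag.topm import AlignStatus


def _small_cfg(**kw):
    base = dict(seed=21, ref_length=60_000, site_spacing=2000, n_taxa=12,
                n_snps=20, mean_depth=4.0, error_rate=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestReference:
    def test_cut_site_list_matches_regex_scan(self):
        cfg = _small_cfg()
        truth = generate_reference(cfg)
        found = []
        for chrom, seq in truth.reference.items():
            found += [(chrom, m.start()) for m in re.finditer(r"(?=(GC[AT]GC))", seq)]
        assert sorted(found) == sorted(truth.cut_sites)
        assert len(found) > 0

    def test_exactly_the_planted_sites_exist(self):
        cfg = _small_cfg(ref_length=30_000, site_spacing=3000)
        truth = generate_reference(cfg)
        assert len(truth.cut_sites) == len({p for _, p in truth.cut_sites})
        # each site spawns a locus per strand
        assert len(truth.loci) == 2 * len(truth.cut_sites)

    def test_determinism(self):
        a = generate_reference(_small_cfg())
        b = generate_reference(_small_cfg())
        assert a.reference == b.reference and a.cut_sites == b.cut_sites

    def test_zero_sites(self):
        cfg = _small_cfg(ref_length=500, site_spacing=10_000, n_snps=0)
        truth = generate_reference(cfg)
        assert truth.cut_sites == [] and truth.loci == []


class TestPopulation:
    def test_fully_inbred_limit_has_no_heterozygotes(self):
        cfg = _small_cfg(inbred_fraction=1.0, selfing_generations=40)
        truth = generate_reference(cfg)
        simulate_population(cfg, truth)
        assert not (truth.genotypes == G_HET).any()

    def test_ril_families_segregate_one_to_one(self):
        cfg = _small_cfg(n_taxa=200, n_families=1, family_size=200, n_snps=40)
        truth = generate_reference(cfg)
        simulate_population(cfg, truth)
        n = truth.genotypes.shape[1]
        for j in range(len(truth.snps)):
            g = truth.genotypes[j]
            alt = (g == 2).sum() + 0.5 * (g == 1).sum()
            freq = alt / n
            if 0.0 < freq < 1.0:  # segregating in this family
                se = np.sqrt(0.25 / n)
                assert abs(freq - 0.5) < 4 * se

    def test_determinism(self):
        cfg = _small_cfg()
        a = simulate_population(cfg, generate_reference(cfg))
        b = simulate_population(cfg, generate_reference(cfg))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert [(s.chrom, s.pos) for s in a.snps] == [(s.chrom, s.pos) for s in b.snps]

    def test_snps_lie_inside_tag_footprints(self):
        cfg = _small_cfg()
        truth = simulate_population(cfg, generate_reference(cfg))
        covered = set()
        for loc in truth.loci:
            covered.update((loc.chrom, p) for p in range(loc.start0, loc.end0))
        for s in truth.snps:
            assert (s.chrom, s.pos - 1) in covered
            assert truth.reference[s.chrom][s.pos - 1] == s.ref_allele


class TestReads:
    def _emit(self, tmp_path, **kw):
        cfg = _small_cfg(**kw)
        truth = simulate_population(cfg, generate_reference(cfg))
        fq = tmp_path / "r.fastq"
        simulate_gbs_fastq(cfg, truth, fq)
        return cfg, truth, fq

    def test_error_free_reads_all_classify_good(self, tmp_path, apeki):
        cfg, truth, fq = self._emit(tmp_path)
        key_path = tmp_path / "key.tsv"
        write_key_file(truth, key_path)
        key = parse_barcode_key(key_path)
        clf = LaneClassifier(key.lane_entries(cfg.flowcell, cfg.lane), apeki)
        statuses = [clf.classify(seq).status for _, seq in iter_fastq(fq)]
        assert statuses and all(s is ReadStatus.GOOD for s in statuses)

    def test_injected_error_rate_matches_counting_oracle(self, tmp_path):
        cfg, truth, fq = self._emit(tmp_path, error_rate=0.01, n_taxa=24, mean_depth=6.0)
        # recount mismatches against independently reconstructed error-free
        # haplotype sequences, read by read
        from gbstag.simdata import _locus_haplotype

        mismatches = bases = 0
        reads = [seq for _, seq in iter_fastq(fq)]
        assert len(reads) == len(truth.reads)
        remnant = 4
        for read, rec in zip(reads, truth.reads):
            taxon = truth.taxa[rec.taxon]
            loc = truth.loci[rec.locus]
            alleles = {}
            for sid in loc.snp_ids:
                g = truth.genotypes[sid, rec.taxon]
                alleles[sid] = rec.haplotype if g == G_HET else (1 if g == 2 else 0)
            clean = _locus_haplotype(truth, loc, alleles)
            tagread = read[len(truth.barcodes[taxon]):]
            assert len(tagread) == len(clean)
            mismatches += sum(a != b for a, b in zip(tagread[remnant:], clean[remnant:]))
            bases += len(clean) - remnant
        rate = mismatches / bases
        se = np.sqrt(0.01 * 0.99 / bases)
        assert abs(rate - 0.01) < 4 * se

    def test_blank_taxa_emit_no_reads(self, tmp_path):
        cfg, truth, fq = self._emit(tmp_path, n_taxa=12, n_blanks=3)
        blank_idx = {i for i, t in enumerate(truth.taxa) if t.startswith("BLANK")}
        assert blank_idx
        assert all(r.taxon not in blank_idx for r in truth.reads)

    def test_outputs_are_a_pure_function_of_config(self, tmp_path):
        _, _, fq1 = self._emit(tmp_path / "a" if (tmp_path / "a").mkdir() or True else None)
        _, _, fq2 = self._emit(tmp_path / "b" if (tmp_path / "b").mkdir() or True else None)
        assert fq1.read_bytes() == fq2.read_bytes()


class TestTruthSam:
    def test_placements_match_reference_sequence(self, tmp_path, clean_run):
        """Independent oracle: each UNIQUE tag's sequence must equal the
        reference slice at its recorded coordinates (reverse-complemented
        on the minus strand), up to alt alleles at true SNP positions."""
        truth = clean_run.truth
        snp_alt = {(s.chrom, s.pos - 1): s.alt_allele for s in truth.snps}
        checked = 0
        for e in clean_run.topm.iter_by_position():
            seq = e.tag.sequence
            ref = truth.reference[e.chrom]
            if e.strand == "+":
                ref_slice = ref[e.cut_pos - 1 : e.cut_pos - 1 + e.tag.length]
                coords = range(e.cut_pos - 1, e.cut_pos - 1 + e.tag.length)
                tag_sense = seq
            else:
                ref_slice = ref[e.cut_pos - e.tag.length : e.cut_pos]
                coords = range(e.cut_pos - e.tag.length, e.cut_pos)
                tag_sense = revcomp(seq)
            for pos0, got, want in zip(coords, tag_sense, ref_slice):
                if got != want:
                    assert snp_alt.get((e.chrom, pos0)) == got
            checked += 1
        assert checked > 0

    def test_paralog_pairs_collapse_onto_one_position(self, noisy_run):
        truth = noisy_run.truth
        for a, b in noisy_run.paralog_pairs:
            la, lb = truth.loci[a], truth.loci[b]
            keys = {(e.chrom, e.strand, e.cut_pos) for e in noisy_run.topm.iter_by_position()}
            assert (lb.chrom, lb.strand, lb.cut_pos) not in keys
            assert (la.chrom, la.strand, la.cut_pos) in keys

    def test_ambiguous_tags_become_multiple(self, tmp_path):
        """A tag sequence generated by two different loci must not be
        assigned a unique position."""
        cfg = _small_cfg()
        truth = simulate_population(cfg, generate_reference(cfg))
        fq = tmp_path / "r.fastq"
        simulate_gbs_fastq(cfg, truth, fq)
        # forge an ambiguity: pretend one master tag arose from two loci
        from gbstag.seqcore import parse_barcode_key as pbk
        from gbstag import tagcounts
        key_path = tmp_path / "key.tsv"
        write_key_file(truth, key_path)
        key = pbk(key_path)
        table, _ = tagcounts.count_tags(fq, key, cfg.enzyme_model, cfg.flowcell, cfg.lane)
        master = tagcounts.merge_tag_counts([table], min_count=1)
        some_seq = master.tags()[0].sequence
        truth.tag_origin[some_seq] = {0, 2}
        sam = tmp_path / "amb.sam"
        write_truth_sam(master, truth, sam)
        from gbstag.topm import import_sam
        topm = import_sam(sam, master)
        entry = topm.lookup(master.tags()[0])
        assert entry.status is AlignStatus.MULTIPLE
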