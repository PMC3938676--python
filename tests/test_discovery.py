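"""TagLocus grouping, tag alignment, genotype calling, site statistics
and SNP filtering."""

import math
import random

import numpy as np
import pytest
from scipy.stats import binom

from gbstag.discovery import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    FilterConfig,
    SNPCandidate,
    TagLocus,
    align_tag_locus,
    call_genotype,
    compute_site_stats,
    discover_snps,
    group_tag_loci,
    nw_align,
    passes_filters,
    run_discovery,
)
from gbstag.seqcore import encode_sequence
from gbstag.tbt import TBT
from gbstag.topm import TOPM, AlignStatus, TOPMEntry, write_topm_binary


# --- independent pairwise alignment oracle ----------------------------------

def oracle_nw_score(a, b, match=2, mismatch=-1, gap=-3):
    """Plain dict-based DP for global alignment with anchored starts and
    free trailing gaps; written independently of the implementation."""
    score = {(0, 0): 0}
    for i in range(1, len(a) + 1):
        score[(i, 0)] = gap * i
    for j in range(1, len(b) + 1):
        score[(0, j)] = gap * j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            score[(i, j)] = max(
                score[(i - 1, j - 1)] + (match if a[i - 1] == b[j - 1] else mismatch),
                score[(i - 1, j)] + gap,
                score[(i, j - 1)] + gap,
            )
    best = max(
        [score[(len(a), j)] for j in range(len(b) + 1)]
        + [score[(i, len(b))] for i in range(len(a) + 1)]
    )
    return best


def alignment_score(ga, gb, match=2, mismatch=-1, gap=-3):
    """Score of a gapped pair, trailing gap columns free."""
    end = len(ga)
    while end > 0 and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    s = 0
    for x, y in zip(ga[:end], gb[:end]):
        if x == "-" or y == "-":
            s += gap
        elif x == y:
            s += match
        else:
            s += mismatch
    return s


# --- grouping ---------------------------------------------------------------


def _unique(seq, chrom, strand, pos):
    return TOPMEntry(encode_sequence(seq), AlignStatus.UNIQUE, chrom=chrom, strand=strand, cut_pos=pos)


class TestGrouping:
    def test_partition_by_position(self):
        seqs_a = ["CAGC" + b * 20 for b in "ACGTA"[:4]] + ["CAGC" + "AC" * 10]
        seqs_b = ["CTGC" + "GT" * 10, "CTGC" + "TT" * 10]
        entries = [_unique(s, "chr1", "+", 100) for s in set(seqs_a)]
        entries += [_unique(s, "chr1", "+", 900) for s in seqs_b]
        topm = TOPM(entries)
        tags = sorted(e.tag for e in entries)
        tbt = TBT(tags, ["t1"])
        loci = group_tag_loci(topm, tbt)
        assert [len(l) for l in loci] == [5, 2]
        assert loci[0].cut_pos == 100 and loci[1].cut_pos == 900

    def test_opposite_strands_are_distinct_loci(self):
        entries = [
            _unique("CAGC" + "AC" * 10, "chr1", "+", 500),
            _unique("CTGC" + "GT" * 10, "chr1", "-", 500),
        ]
        topm = TOPM(entries)
        tbt = TBT(sorted(e.tag for e in entries), ["t1"])
        assert len(group_tag_loci(topm, tbt)) == 2

    def test_unplaced_tags_join_no_locus(self):
        entries = [
            _unique("CAGC" + "AC" * 10, "chr1", "+", 500),
            TOPMEntry(encode_sequence("CAGC" + "GG" * 10), AlignStatus.MULTIPLE),
            TOPMEntry(encode_sequence("CAGC" + "TT" * 10), AlignStatus.UNALIGNED),
        ]
        topm = TOPM(entries)
        tbt = TBT(sorted(e.tag for e in entries), ["t1"])
        loci = group_tag_loci(topm, tbt)
        assert len(loci) == 1 and len(loci[0]) == 1


# --- pairwise alignment -----------------------------------------------------


class TestAlignment:
    def test_identical_sequences_align_gap_free(self):
        s = "CAGC" + "AT" * 8
        score, ga, gb = nw_align(s, s)
        assert ga == gb == s
        assert score == 2 * len(s)

    def test_single_substitution(self):
        a = "CAGCAAAATTTTGGGG"
        b = "CAGCAAAACTTTGGGG"
        score, ga, gb = nw_align(a, b)
        assert "-" not in ga + gb
        assert sum(x != y for x, y in zip(ga, gb)) == 1
        assert score == 2 * 15 - 1

    def test_two_base_deletion_places_two_gaps(self):
        a = "CAGCAAAATTTTGGGGCC"
        b = "CAGCAAAATTGGGGCC"  # TT deleted
        score, ga, gb = nw_align(a, b)
        assert gb.count("-") == 2 and ga.count("-") == 0
        assert score == oracle_nw_score(a, b)

    def test_random_pairs_match_oracle_score(self):
        rng = random.Random(61)
        for _ in range(120):
            stem = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 10)))
            a = stem + "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 22)))
            b = stem + "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 22)))
            score, ga, gb = nw_align(a, b)
            assert alignment_score(ga, gb) == score == oracle_nw_score(a, b)
            assert ga.replace("-", "") == a and gb.replace("-", "") == b

    def test_locus_alignment_rows_ungap_to_tags(self):
        tags = [encode_sequence(s) for s in ("CAGCAATTGG", "CAGCAAGTGG", "CAGCAATT")]
        locus = TagLocus("chr1", "+", 10, tags, [0, 1, 2])
        aln = align_tag_locus(locus)
        assert len({len(r) for r in aln.rows}) == 1
        for tag, row in zip(tags, aln.rows):
            assert row.replace("-", "") == tag.sequence

    def test_two_tag_locus_achieves_optimal_pair_score(self):
        rng = random.Random(67)
        for _ in range(50):
            stem = "CAGC"
            a = stem + "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 28)))
            b = stem + "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 28)))
            if a == b:
                continue
            tags = [encode_sequence(a), encode_sequence(b)]
            locus = TagLocus("chr1", "+", 10, tags, [0, 1])
            aln = align_tag_locus(locus, weights=[2, 1])
            assert alignment_score(aln.rows[0], aln.rows[1]) == oracle_nw_score(a, b)


# --- genotype calling -------------------------------------------------------


def oracle_call(d_major, d_minor, err=0.01, lr_threshold=1.0):
    """Independent three-likelihood comparison via scipy binomial pmfs."""
    n = d_major + d_minor
    if n == 0:
        return MISSING
    l_hom_major = binom.pmf(d_minor, n, err)
    l_hom_minor = binom.pmf(d_major, n, err)
    l_het = binom.pmf(d_major, n, 0.5)
    best_hom = max(l_hom_major, l_hom_minor)
    code = HOM_MAJOR if l_hom_major >= l_hom_minor else HOM_MINOR
    if l_het >= best_hom or best_hom < lr_threshold * l_het:
        return HET
    return code


class TestCallGenotype:
    def test_clean_homozygote(self):
        # depths (5, 0): L_hom = 0.99^5 ~ 0.951 dwarfs L_het = 0.5^5
        assert call_genotype(5, 0) == HOM_MAJOR
        assert math.isclose(0.99**5, 0.9509900499)

    def test_balanced_heterozygote(self):
        # depths (3, 3): L_het = 0.5^6 ~ 0.0156 dwarfs L_hom ~ 9.4e-7
        assert call_genotype(3, 3) == HET

    def test_no_evidence_is_missing(self):
        assert call_genotype(0, 0) == MISSING

    def test_minor_majority_calls_minor_homozygote(self):
        assert call_genotype(0, 6) == HOM_MINOR

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            call_genotype(-1, 2)
        with pytest.raises(ValueError):
            call_genotype(2, 2, err=0.6)

    @pytest.mark.parametrize("err,lr", [(0.01, 1.0), (0.001, 1.0), (0.05, 2.0)])
    def test_matches_enumeration_oracle(self, err, lr):
        for n in range(0, 26):
            for dm in range(0, n + 1):
                assert call_genotype(n - dm, dm, err, lr) == oracle_call(n - dm, dm, err, lr), (n - dm, dm)

    def test_lr_threshold_pushes_marginal_calls_to_het(self):
        # single read: pure ML calls homozygote; a stringent ratio demands more
        assert call_genotype(1, 0) == HOM_MAJOR
        assert call_genotype(1, 0, lr_threshold=3.0) == HET


# --- SNP discovery on constructed loci --------------------------------------


def _two_tag_setup(depths_by_taxon):
    """Two 20 bp tags differing at offset 10; depths_by_taxon maps taxon
    name -> (depth of tag A, depth of tag B)."""
    a = "CAGCAA" + "TTTT" + "A" + "GGGGCCCCA"
    b = "CAGCAA" + "TTTT" + "C" + "GGGGCCCCA"
    tags = sorted([encode_sequence(a), encode_sequence(b)])
    taxa = list(depths_by_taxon)
    mat = np.zeros((2, len(taxa)), dtype=np.uint8)
    for t, (da, db) in enumerate(depths_by_taxon.values()):
        ai = tags.index(encode_sequence(a))
        bi = tags.index(encode_sequence(b))
        mat[ai, t] = da
        mat[bi, t] = db
    tbt = TBT(tags, taxa, mat)
    locus = TagLocus("chr1", "+", 100, tags, [0, 1])
    return locus, tbt, (a, b)


class TestDiscoverSnps:
    def test_single_snp_with_mixed_genotypes(self):
        locus, tbt, _ = _two_tag_setup({"t1": (4, 0), "t2": (0, 4), "t3": (2, 2), "t4": (0, 0)})
        aln = align_tag_locus(locus, weights=[int(r.sum()) for r in tbt.depths])
        (cand,) = discover_snps(aln, tbt)
        assert cand.column == 10
        assert cand.pos == 110
        by_taxon = dict(zip(tbt.taxa, cand.calls))
        hom_codes = {by_taxon["t1"], by_taxon["t2"]}
        assert hom_codes == {HOM_MAJOR, HOM_MINOR}
        assert by_taxon["t3"] == HET
        assert by_taxon["t4"] == MISSING

    def test_identical_tags_yield_no_candidates(self):
        s = "CAGC" + "AT" * 8
        tags = [encode_sequence(s)]
        tbt = TBT(tags, ["t1"], np.array([[5]], dtype=np.uint8))
        locus = TagLocus("chr1", "+", 100, tags, [0])
        aln = align_tag_locus(locus)
        assert discover_snps(aln, tbt) == []

    def test_triallelic_column(self):
        base = "CAGCAATTTT"
        seqs = [base + x + "GGGGCCCCA" for x in "ACT"]
        tags = sorted(encode_sequence(s) for s in seqs)
        mat = np.array([[6, 0, 0], [0, 3, 0], [0, 0, 1]], dtype=np.uint8)
        tbt = TBT(tags, ["t1", "t2", "t3"], mat)
        locus = TagLocus("chr1", "+", 100, tags, [0, 1, 2])
        aln = align_tag_locus(locus, weights=[6, 3, 1])
        (cand,) = discover_snps(aln, tbt)
        assert len(cand.alleles) == 3
        # taxon carrying only the third allele is missing at the biallelic call
        third = cand.alleles[2]
        carrier = int(np.argmax(cand.depths[2]))
        assert cand.calls[carrier] == MISSING

    def test_allele_depth_conservation(self):
        locus, tbt, _ = _two_tag_setup({"t1": (3, 2), "t2": (1, 7), "t3": (0, 5)})
        aln = align_tag_locus(locus, weights=[int(r.sum()) for r in tbt.depths])
        (cand,) = discover_snps(aln, tbt)
        member_depth = tbt.depths.astype(int).sum(axis=0)
        assert list(cand.depths.sum(axis=0)) == list(member_depth)

    def test_minus_strand_candidates_use_reference_sense_alleles(self):
        a = "CAGCAA" + "TTTT" + "A" + "GGGGCCCCA"
        b = "CAGCAA" + "TTTT" + "C" + "GGGGCCCCA"
        tags = sorted([encode_sequence(a), encode_sequence(b)])
        mat = np.array([[4], [4]], dtype=np.uint8)
        tbt = TBT(tags, ["t1"], mat)
        locus = TagLocus("chr1", "-", 500, tags, [0, 1])
        aln = align_tag_locus(locus, weights=[4, 4])
        (cand,) = discover_snps(aln, tbt)
        assert cand.pos == 500 - 10
        assert set(cand.alleles) == {"T", "G"}  # complements of A/C


# --- site statistics --------------------------------------------------------


def _candidate(calls, depths=None, locus_coverage=1.0):
    calls = np.array(calls, dtype=np.int8)
    n = len(calls)
    if depths is None:
        depths = np.full((2, n), 2, dtype=np.int64)
    return SNPCandidate(
        chrom="chr1", pos=100, strand="+", column=0,
        alleles=["A", "C"], depths=np.asarray(depths), calls=calls,
        locus_coverage=locus_coverage,
    )


class TestSiteStats:
    def test_fully_inbred_site_has_unit_fit(self):
        calls = [HOM_MAJOR] * 6 + [HOM_MINOR] * 2
        taxa = [f"i{k}" for k in range(8)]
        stats = compute_site_stats(_candidate(calls), taxa, {t: 1.0 for t in taxa}, 0.8)
        assert stats.q == 0.25 and stats.ho == 0.0 and stats.f_it == 1.0

    def test_inbred_het_score_formula(self):
        # 1 het, 1 deep minor homozygote, 2 major homozygotes -> 1/(1+1+0.5)
        calls = [HET, HOM_MINOR, HOM_MAJOR, HOM_MAJOR]
        depths = np.array([[1, 0, 3, 3], [1, 4, 0, 0]])
        taxa = [f"i{k}" for k in range(4)]
        stats = compute_site_stats(_candidate(calls, depths), taxa, {t: 1.0 for t in taxa}, 0.8)
        assert stats.n_inbred_hets == 1
        assert stats.n_inbreds_gt1read_homo_min == 1
        assert stats.inbred_het_score == pytest.approx(1 / 2.5)

    def test_panmictic_site_has_zero_fit(self):
        calls = [HOM_MAJOR, HOM_MINOR, HET, HET]
        stats = compute_site_stats(_candidate(calls), ["a", "b", "c", "d"])
        assert stats.q == 0.5 and stats.ho == 0.5
        assert stats.f_it == pytest.approx(0.0)

    def test_monomorphic_site_has_undefined_fit(self):
        stats = compute_site_stats(_candidate([HOM_MAJOR] * 5), list("abcde"))
        assert stats.he == 0.0 and stats.f_it is None
        assert not passes_filters(stats, FilterConfig(), has_pedigree=False)

    def test_pedigree_restricts_the_scored_subpopulation(self):
        calls = [HOM_MAJOR, HOM_MINOR] + [HET] * 6
        taxa = [f"t{k}" for k in range(8)]
        pedigree = {"t0": 1.0, "t1": 1.0}  # only the two homozygotes are inbred
        stats = compute_site_stats(_candidate(calls), taxa, pedigree, 0.8)
        assert stats.ho == 0.0 and stats.q == 0.5
        assert stats.inbred_coverage == 1.0


class TestFilters:
    def test_low_maf_rejected(self):
        stats = compute_site_stats(_candidate([HOM_MAJOR] * 999 + [HET]), [f"t{k}" for k in range(1000)])
        assert stats.q == pytest.approx(0.0005)
        assert not passes_filters(stats, FilterConfig(min_maf=0.001, min_fit=-10), has_pedigree=False)

    def test_paralog_like_excess_heterozygosity_rejected(self):
        stats = compute_site_stats(_candidate([HET] * 8), [f"t{k}" for k in range(8)])
        assert stats.f_it == pytest.approx(-1.0)
        assert not passes_filters(stats, FilterConfig(), has_pedigree=False)

    def test_vacuous_thresholds_retain_everything(self):
        cfg = FilterConfig(min_maf=0.0, min_fit=-1e9, min_inbred_coverage=-1.0,
                           max_inbred_het_score=1e9, min_locus_coverage=0.0)
        calls_sets = [
            [HET] * 8,
            [HOM_MAJOR] * 7 + [HOM_MINOR],
            [HOM_MAJOR, HOM_MINOR, HET, MISSING],
        ]
        taxa = [f"t{k}" for k in range(8)]
        for calls in calls_sets:
            calls = calls + [MISSING] * (8 - len(calls))
            stats = compute_site_stats(_candidate(calls), taxa, {t: 1.0 for t in taxa}, 0.8)
            if stats.he > 0:
                assert passes_filters(stats, cfg, has_pedigree=True)

    def test_tightening_any_threshold_is_monotone(self):
        rng = random.Random(71)
        taxa = [f"t{k}" for k in range(12)]
        pedigree = {t: 1.0 for t in taxa[:8]}
        cands = []
        for _ in range(60):
            calls = [rng.choice([HOM_MAJOR, HOM_MAJOR, HOM_MINOR, HET, MISSING]) for _ in taxa]
            cands.append(_candidate(calls, locus_coverage=rng.random()))
        stats = [compute_site_stats(c, taxa, pedigree, 0.8) for c in cands]
        base = FilterConfig(min_maf=0.01, min_fit=0.2, min_inbred_coverage=0.1,
                            max_inbred_het_score=0.5, min_locus_coverage=0.2)
        kept = {i for i, s in enumerate(stats) if passes_filters(s, base, True)}
        tighter = [
            FilterConfig(min_maf=0.1, min_fit=0.2, min_inbred_coverage=0.1,
                         max_inbred_het_score=0.5, min_locus_coverage=0.2),
            FilterConfig(min_maf=0.01, min_fit=0.8, min_inbred_coverage=0.1,
                         max_inbred_het_score=0.5, min_locus_coverage=0.2),
            FilterConfig(min_maf=0.01, min_fit=0.2, min_inbred_coverage=0.4,
                         max_inbred_het_score=0.5, min_locus_coverage=0.2),
            FilterConfig(min_maf=0.01, min_fit=0.2, min_inbred_coverage=0.1,
                         max_inbred_het_score=0.2, min_locus_coverage=0.2),
            FilterConfig(min_maf=0.01, min_fit=0.2, min_inbred_coverage=0.1,
                         max_inbred_het_score=0.5, min_locus_coverage=0.6),
        ]
        for cfg in tighter:
            sub = {i for i, s in enumerate(stats) if passes_filters(s, cfg, True)}
            assert sub <= kept


class TestParameterRecovery:
    def test_standard_filters_cut_error_and_reject_paralogs_at_low_error(self, noisy_run_low):
        """At 0.1% per-base error with paralog-merged loci, retained-SNP
        genotype error is lower under the standard filters than under a
        MAF-only filter, and merged loci show negative F_IT."""
        from gbstag.evaluate import genotype_error_rate
        from gbstag.production import genotype_table_from_discovery

        run = noisy_run_low
        maf_cfg = FilterConfig(
            min_maf=0.001, min_fit=-np.inf, min_inbred_coverage=-np.inf,
            max_inbred_het_score=np.inf, min_locus_coverage=0.0,
        )
        _t, rep_std = run_discovery(run.topm, run.tbt, pedigree=run.truth.pedigree)
        _t, rep_maf = run_discovery(run.topm, run.tbt, pedigree=run.truth.pedigree, cfg=maf_cfg)
        err_std = genotype_error_rate(genotype_table_from_discovery(rep_std), run.truth)
        err_maf = genotype_error_rate(genotype_table_from_discovery(rep_maf), run.truth)
        assert err_std < err_maf
        merged = run.merged_locus_keys
        checked = 0
        for lr in rep_maf.loci:
            if (lr.locus.chrom, lr.locus.strand, lr.locus.cut_pos) in merged:
                for stats in lr.stats:
                    checked += 1
                    assert stats.f_it is None or stats.f_it < 0
        assert checked > 0


class TestRunDiscovery:
    def test_rerun_is_byte_identical(self, clean_run, tmp_path):
        t1, _ = run_discovery(clean_run.topm, clean_run.tbt, pedigree=clean_run.truth.pedigree)
        t2, _ = run_discovery(clean_run.topm, clean_run.tbt, pedigree=clean_run.truth.pedigree)
        p1, p2 = tmp_path / "a.topm", tmp_path / "b.topm"
        write_topm_binary(t1, p1)
        write_topm_binary(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_reject_everything_config_annotates_nothing(self, clean_run):
        cfg = FilterConfig(min_maf=0.6)  # unattainable: q <= 0.5 by definition
        topm_prod, report = run_discovery(clean_run.topm, clean_run.tbt, cfg=cfg)
        assert report.n_retained == 0
        assert topm_prod.annotated_entries() == []

    def test_variants_annotated_for_every_retained_locus(self, clean_discovery):
        topm_prod, report = clean_discovery
        for lr in report.loci:
            if not lr.retained:
                continue
            cols = {lr.candidates[i].column for i in lr.retained}
            for tag, row in zip(lr.locus.tags, lr.alignment.rows):
                entry = topm_prod.lookup(tag)
                assert {v.offset for v in entry.variants} == cols
                for v in entry.variants:
                    assert v.allele == row[v.offset]
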