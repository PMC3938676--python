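"""Deterministic synthetic GBS data with full truth tables.

Emulates the assay end to end at desk scale: a reference with planted
restriction cut sites (and none elsewhere), diploid populations of inbred,
outbred and biparental RIL taxa with known genotypes, and multiplexed
FASTQ reads of the canonical anatomy barcode + cut-site remnant + genomic
sequence, with per-taxon per-locus depths drawn from a Poisson and
substitution sequencing errors at a configurable rate.  Because every
read, tag and genotype traces back to the truth tables, every pipeline
stage can be verified without external data.

A truth-based SAM writer stands in for the external aligner: each master
tag is placed at the locus that generated it.  Assigning two reference
loci the same position through ``paralog_pairs`` emulates paralog-merged
loci (the failure mode the F_IT filter exists to catch).

The default configuration mirrors the assay's intended regime: a 1 Mb
reference with roughly ApeKI-density cut sites, 96 taxa, mean per-taxon
per-locus depth 2 (the low-coverage 0.5-3x regime), and 500 true SNPs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seqcore import EnzymeModel, load_enzyme, revcomp, MAX_TAG_LENGTH
from .tagcounts import MasterTagList

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Truth genotype codes
G_HOM_REF = 0
G_HET = 1
G_HOM_ALT = 2


@dataclass
class SimConfig:
    seed: int = 0
    ref_length: int = 1_000_000
    n_contigs: int = 1
    enzyme: str = "ApeKI"
    site_spacing: int = 1000          # expected distance between cut sites
    n_taxa: int = 96
    inbred_fraction: float = 0.8
    n_families: int = 0               # biparental F2-derived RIL families
    family_size: int = 30
    selfing_generations: int = 5      # residual heterozygosity = 0.5**g
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.1, 0.5)
    mean_depth: float = 2.0
    error_rate: float = 0.0
    barcode_length: int = 6
    flowcell: str = "SIMFLOW"
    lane: str = "1"
    n_blanks: int = 0
    errors_in_barcode: bool = False   # by default errors never hit barcode/remnant
    trim_length: int = MAX_TAG_LENGTH

    def __post_init__(self):
        if not 0 < self.mean_depth:
            raise ValueError("mean_depth must be > 0")
        for p in (self.inbred_fraction, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def enzyme_model(self) -> EnzymeModel:
        return load_enzyme(self.enzyme)


@dataclass
class LocusTruth:
    chrom: str
    strand: str
    cut_pos: int       # 1-based; leftmost tag base (+) / rightmost (-)
    start0: int        # 0-based reference slice start of the tag footprint
    end0: int          # 0-based exclusive end
    snp_ids: list[int] = field(default_factory=list)


@dataclass
class SNPTruth:
    chrom: str
    pos: int           # 1-based
    ref_allele: str
    alt_allele: str
    freq: float        # alt-allele population frequency


@dataclass
class ReadRecord:
    taxon: int
    locus: int
    haplotype: int
    n_errors: int


@dataclass
class TruthSet:
    config: SimConfig
    reference: dict[str, str]
    cut_sites: list[tuple[str, int]]          # (chrom, 0-based site start)
    loci: list[LocusTruth]
    snps: list[SNPTruth] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)
    genotypes: Optional[np.ndarray] = None    # (n_snps, n_taxa) truth codes
    families: dict[str, str] = field(default_factory=dict)
    pedigree: dict[str, float] = field(default_factory=dict)
    barcodes: dict[str, str] = field(default_factory=dict)
    tag_origin: dict[str, set[int]] = field(default_factory=dict)
    reads: list[ReadRecord] = field(default_factory=list)


def _site_pattern(enzyme: EnzymeModel) -> str:
    # Recognition site = one leading base + the remnant (e.g. G + CWGC).
    # Built from the enzyme's internal chimera patterns, which are the
    # full recognition sites.
    pats = enzyme.internal_patterns
    if not pats:
        raise ValueError("enzyme has no internal pattern to derive a site from")
    return pats[0]


_IUPAC_CHOICES = {"W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "N": "ACGT"}


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else _IUPAC_CHOICES[c][rng.integers(len(_IUPAC_CHOICES[c]))]
        for c in pattern
    )


def _pattern_regex(enzyme: EnzymeModel) -> re.Pattern:
    from .seqcore import _IUPAC

    alts = ["".join(_IUPAC[c] for c in p) for p in enzyme.internal_patterns]
    return re.compile("(?=(" + "|".join(alts) + "))")


def generate_reference(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Random reference with cut sites planted at ~``site_spacing`` and
    destroyed everywhere else, plus the exact cut-site list."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    enzyme = cfg.enzyme_model
    pattern = _site_pattern(enzyme)
    regex = _pattern_regex(enzyme)
    reference: dict[str, str] = {}
    cut_sites: list[tuple[str, int]] = []
    loci: list[LocusTruth] = []
    contig_len = cfg.ref_length // cfg.n_contigs
    for ci in range(cfg.n_contigs):
        chrom = f"chr{ci + 1}"
        seq = _BASES[rng.integers(0, 4, size=contig_len)].tobytes().decode()
        # choose planted positions before scrubbing accidental sites
        n_sites = max(0, contig_len // cfg.site_spacing)
        positions: list[int] = []
        pos = 0
        margin = MAX_TAG_LENGTH + 8
        for _ in range(n_sites):
            jitter = int(rng.integers(-cfg.site_spacing // 4, cfg.site_spacing // 4 + 1))
            pos += cfg.site_spacing + jitter
            if pos < margin:
                pos = margin + int(rng.integers(0, 8))
            if pos + len(pattern) + margin > contig_len:
                break
            if positions and pos - positions[-1] < 2 * len(pattern):
                continue
            positions.append(pos)
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        for p in positions:
            site = _concretize(pattern, rng)
            arr[p : p + len(site)] = np.frombuffer(site.encode(), dtype="S1")
        seq = arr.tobytes().decode()
        seq = _scrub_accidental_sites(seq, regex, set(positions), len(pattern), rng)
        reference[chrom] = seq
        plen = len(pattern)
        for p in sorted(positions):
            cut_sites.append((chrom, p))
            # + strand tag: starts one base into the site (after the leading
            # G), remnant first; footprint p+1 .. p+1+64
            loci.append(LocusTruth(chrom, "+", p + 2, p + 1, min(p + 1 + cfg.trim_length, len(seq))))
            # - strand tag: reverse-complement ending at the site's last base
            loci.append(LocusTruth(chrom, "-", p + plen - 1, max(0, p + plen - 1 - cfg.trim_length), p + plen - 1))
    return TruthSet(cfg, reference, cut_sites, loci)


def _scrub_accidental_sites(
    seq: str, regex: re.Pattern, planted: set[int], plen: int, rng: np.random.Generator
) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for _ in range(20):
        text = arr.tobytes().decode()
        dirty = [m.start() for m in regex.finditer(text) if m.start() not in planted]
        if not dirty:
            return text
        for p in dirty:
            # mutate a middle base; never touch a planted core
            for off in (plen // 2, plen // 2 + 1, 1):
                idx = p + off
                if not any(q <= idx < q + plen for q in planted):
                    old = arr[idx]
                    choices = [b for b in b"ACGT" if bytes([b]) != old]
                    arr[idx] = bytes([choices[int(rng.integers(3))]])
                    break
    text = arr.tobytes().decode()
    leftover = [m.start() for m in regex.finditer(text) if m.start() not in planted]
    if leftover:
        raise RuntimeError("could not scrub accidental cut sites")
    return text


# ---------------------------------------------------------------------------
# Population simulation


def _eligible_snp_positions(truth: TruthSet) -> list[tuple[str, int]]:
    """0-based reference positions covered by a tag footprint but outside
    every recognition-site core (so substitutions cannot create or destroy
    a cut site at the core) and outside the remnant bases."""
    plen = len(_site_pattern(truth.config.enzyme_model))
    cores: dict[str, set[int]] = {c: set() for c in truth.reference}
    for chrom, p in truth.cut_sites:
        # wide margin: a substitution near a planted site must not be able
        # to interact with it when checking for accidental site creation
        cores[chrom].update(range(p - plen - 6, p + plen + 7))
    eligible: set[tuple[str, int]] = set()
    for loc in truth.loci:
        for i in range(loc.start0, loc.end0):
            if i not in cores[loc.chrom]:
                eligible.add((loc.chrom, i))
    return sorted(eligible)


def simulate_population(cfg: SimConfig, truth: TruthSet, rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Draw true SNPs and per-taxon truth genotypes into ``truth``.

    Taxa layout: RIL families first (``n_families`` x ``family_size``),
    then the remaining taxa split into inbreds (fraction
    ``inbred_fraction``; homozygous up to residual heterozygosity
    0.5**selfing_generations) and outbred taxa in Hardy-Weinberg
    proportions, then ``n_blanks`` blank negative controls.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    enzyme = cfg.enzyme_model
    regex = _pattern_regex(enzyme)
    eligible = _eligible_snp_positions(truth)
    if cfg.n_snps > len(eligible):
        raise ValueError(f"n_snps={cfg.n_snps} exceeds {len(eligible)} tag-covered positions")
    picks = rng.choice(len(eligible), size=cfg.n_snps, replace=False)
    snps: list[SNPTruth] = []
    for k in sorted(picks):
        chrom, i = eligible[k]
        ref_base = truth.reference[chrom][i]
        for _ in range(8):
            alt = "ACGT"[rng.integers(4)]
            if alt == ref_base:
                continue
            window = truth.reference[chrom][max(0, i - 6) : i + 6]
            mutated = window[: i - max(0, i - 6)] + alt + window[i - max(0, i - 6) + 1 :]
            if regex.search(mutated) is None:
                break
        else:
            continue
        freq = float(rng.uniform(*cfg.maf_range))
        snps.append(SNPTruth(chrom, i + 1, ref_base, alt, freq))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    truth.snps = snps
    for loc_id, loc in enumerate(truth.loci):
        loc.snp_ids = [
            j for j, s in enumerate(snps)
            if s.chrom == loc.chrom and loc.start0 <= s.pos - 1 < loc.end0
        ]

    n_ril = cfg.n_families * cfg.family_size
    n_rest = cfg.n_taxa - n_ril - cfg.n_blanks
    if n_rest < 0:
        raise ValueError("n_taxa too small for families + blanks")
    n_inbred = int(round(n_rest * cfg.inbred_fraction))
    taxa: list[str] = []
    pedigree: dict[str, float] = {}
    families: dict[str, str] = {}
    resid = 0.5 ** cfg.selfing_generations
    f_inbred = 1.0 - resid

    n_snps = len(snps)
    geno = np.zeros((n_snps, cfg.n_taxa), dtype=np.int8)
    freqs = np.array([s.freq for s in snps])
    col = 0
    for f in range(cfg.n_families):
        fname = f"FAM{f + 1}"
        p1 = (rng.random(n_snps) < freqs).astype(np.int8)
        p2 = (rng.random(n_snps) < freqs).astype(np.int8)
        for r in range(cfg.family_size):
            name = f"{fname}_RIL{r + 1}"
            taxa.append(name)
            families[name] = fname
            pedigree[name] = f_inbred
            pick = rng.random(n_snps) < 0.5
            alleles = np.where(pick, p1, p2)
            g = np.where(alleles == 1, G_HOM_ALT, G_HOM_REF).astype(np.int8)
            het = (rng.random(n_snps) < resid) & (p1 != p2)
            g[het] = G_HET
            geno[:, col] = g
            col += 1
    for i in range(n_inbred):
        name = f"INBRED{i + 1}"
        taxa.append(name)
        pedigree[name] = f_inbred
        a1 = (rng.random(n_snps) < freqs).astype(np.int8)
        ibd = rng.random(n_snps) >= resid
        a2 = np.where(ibd, a1, (rng.random(n_snps) < freqs).astype(np.int8))
        geno[:, col] = np.where(a1 == a2, np.where(a1 == 1, G_HOM_ALT, G_HOM_REF), G_HET)
        col += 1
    for i in range(n_rest - n_inbred):
        name = f"OUTBRED{i + 1}"
        taxa.append(name)
        pedigree[name] = 0.0
        a1 = (rng.random(n_snps) < freqs).astype(np.int8)
        a2 = (rng.random(n_snps) < freqs).astype(np.int8)
        geno[:, col] = np.where(a1 == a2, np.where(a1 == 1, G_HOM_ALT, G_HOM_REF), G_HET)
        col += 1
    for i in range(cfg.n_blanks):
        name = f"BLANK{i + 1}"
        taxa.append(name)
        pedigree[name] = 0.0
        col += 1
    truth.taxa = taxa
    truth.genotypes = geno
    truth.families = families
    truth.pedigree = pedigree
    return truth


# ---------------------------------------------------------------------------
# Read simulation


def _make_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join("ACGT"[rng.integers(4)] for _ in range(length))
        if bc in seen:
            continue
        seen.add(bc)
        out.append(bc)
    return out


def _locus_haplotype(truth: TruthSet, loc: LocusTruth, alleles: dict[int, int]) -> str:
    """Tag-sense sequence of a locus footprint carrying given SNP alleles."""
    seq = truth.reference[loc.chrom][loc.start0 : loc.end0]
    if alleles:
        arr = list(seq)
        for sid, a in alleles.items():
            s = truth.snps[sid]
            arr[s.pos - 1 - loc.start0] = s.alt_allele if a else s.ref_allele
        seq = "".join(arr)
    return seq if loc.strand == "+" else revcomp(seq)


def simulate_gbs_fastq(
    cfg: SimConfig,
    truth: TruthSet,
    out_fastq,
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Emit multiplexed reads (barcode + remnant-anchored tag) to
    ``out_fastq`` and record per-read provenance in ``truth``.

    Per-taxon per-locus read counts are Poisson(``mean_depth``); each read
    samples one of the taxon's two haplotypes; substitution errors hit
    each base beyond the remnant with probability ``error_rate`` (and the
    barcode/remnant too only if ``errors_in_barcode``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if truth.genotypes is None:
        raise ValueError("simulate_population must run before read simulation")
    barcodes = _make_barcodes(len(truth.taxa), cfg.barcode_length, rng)
    truth.barcodes = dict(zip(truth.taxa, barcodes))
    remnant_len = len(cfg.enzyme_model.remnants[0])
    blank = {i for i, t in enumerate(truth.taxa) if t.startswith("BLANK")}

    lines: list[str] = []
    n_read = 0
    for li, loc in enumerate(truth.loci):
        # Precompute the (few) haplotype sequences this locus can emit.
        hap_cache: dict[tuple, str] = {}
        depths = rng.poisson(cfg.mean_depth, size=len(truth.taxa))
        for ti in range(len(truth.taxa)):
            if ti in blank:
                continue
            for _ in range(int(depths[ti])):
                hap = int(rng.integers(2))
                key_alleles = []
                for sid in loc.snp_ids:
                    g = truth.genotypes[sid, ti]
                    if g == G_HET:
                        key_alleles.append((sid, hap))
                    else:
                        key_alleles.append((sid, 1 if g == G_HOM_ALT else 0))
                key = tuple(key_alleles)
                seq = hap_cache.get(key)
                if seq is None:
                    seq = _locus_haplotype(truth, loc, dict(key_alleles))
                    hap_cache[key] = seq
                n_err = 0
                if cfg.error_rate > 0.0:
                    start = 0 if cfg.errors_in_barcode else remnant_len
                    k = rng.binomial(len(seq) - start, cfg.error_rate)
                    if k:
                        positions = rng.choice(len(seq) - start, size=k, replace=False) + start
                        arr = list(seq)
                        for p in positions:
                            arr[p] = "ACGT"[(("ACGT".index(arr[p])) + 1 + rng.integers(3)) % 4]
                        seq = "".join(arr)
                        n_err = int(k)
                truth.tag_origin.setdefault(seq, set()).add(li)
                truth.reads.append(ReadRecord(ti, li, hap, n_err))
                n_read += 1
                read = truth.barcodes[truth.taxa[ti]] + seq
                lines.append(f"@sim{n_read}\n{read}\n+\n{'F' * len(read)}\n")
    from .seqcore import _open_text

    with _open_text(out_fastq, "wt") as fh:
        fh.write("".join(lines))
    return truth


def write_reference_fasta(truth: TruthSet, path) -> None:
    from .seqcore import _open_text

    with _open_text(path, "wt") as fh:
        for chrom, seq in truth.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_key_file(truth: TruthSet, path) -> None:
    cfg = truth.config
    with open(path, "w") as fh:
        fh.write("Flowcell\tLane\tBarcode\tSample\tLibraryPrepID\n")
        for taxon in truth.taxa:
            fh.write(f"{cfg.flowcell}\t{cfg.lane}\t{truth.barcodes[taxon]}\t{taxon}\t\n")


def write_truth_tables(truth: TruthSet, out_dir) -> None:
    out = Path(out_dir)
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tfreq\n")
        for s in truth.snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.freq:.4f}\n")
    with open(out / "truth_genotypes.tsv", "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(truth.taxa) + "\n")
        for j, s in enumerate(truth.snps):
            row = "\t".join(str(int(g)) for g in truth.genotypes[j])
            fh.write(f"{s.chrom}\t{s.pos}\t{row}\n")
    with open(out / "pedigree.tsv", "w") as fh:
        fh.write("Taxon\tF\n")
        for t in truth.taxa:
            fh.write(f"{t}\t{truth.pedigree.get(t, 0.0):.4f}\n")
    if truth.families:
        with open(out / "families.tsv", "w") as fh:
            fh.write("Taxon\tFamily\n")
            for t, f in truth.families.items():
                fh.write(f"{t}\t{f}\n")


# ---------------------------------------------------------------------------
# Truth-based alignment (stands in for the external aligner)


def write_truth_sam(
    master: MasterTagList,
    truth: TruthSet,
    path,
    paralog_pairs: Optional[list[tuple[int, int]]] = None,
) -> None:
    """Write SAM records for the exported master FASTQ from truth provenance.

    Each master tag is placed at the locus that generated it; tags whose
    sequence arose from more than one locus are emitted as MAPQ-0
    placements (ambiguous), unknown sequences as unmapped.  Entries of
    ``paralog_pairs`` (locus index B -> locus index A) re-assign locus B's
    tags to locus A's coordinates, emulating paralogous loci collapsed
    onto one position by the aligner.
    """
    remap = {b: a for a, b in (paralog_pairs or [])}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in truth.reference.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for i, (tag, count) in enumerate(master.items()):
            seq = tag.sequence
            qname = f"tag{i}|count={count}"
            origins = truth.tag_origin.get(seq)
            if origins is None:
                # try prefix provenance: chimera-trimmed or truncated tags
                origins = set()
                for full, locs in truth.tag_origin.items():
                    if full.startswith(seq):
                        origins |= locs
                if not origins:
                    fh.write(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n")
                    continue
            origins = {remap.get(li, li) for li in origins}
            if len(origins) > 1:
                li = sorted(origins)[0]
                loc = truth.loci[li]
                pos, flag, out_seq = _sam_placement(loc, seq)
                fh.write(
                    f"{qname}\t{flag}\t{loc.chrom}\t{pos}\t0\t{len(seq)}M\t*\t0\t0\t"
                    f"{out_seq}\t{'I' * len(seq)}\n"
                )
                continue
            loc = truth.loci[next(iter(origins))]
            pos, flag, out_seq = _sam_placement(loc, seq)
            fh.write(
                f"{qname}\t{flag}\t{loc.chrom}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t"
                f"{out_seq}\t{'I' * len(seq)}\tAS:i:{2 * len(seq)}\n"
            )


def _sam_placement(loc: LocusTruth, tag_seq: str) -> tuple[int, int, str]:
    if loc.strand == "+":
        return loc.cut_pos, 0, tag_seq
    # minus strand: tag extends leftward from cut_pos; SAM wants the
    # leftmost coordinate and the reference-sense sequence
    return loc.cut_pos - len(tag_seq) + 1, 16, revcomp(tag_seq)


def paralog_pair_candidates(truth: TruthSet, n_pairs: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pick ``n_pairs`` disjoint same-strand locus pairs (A, B) whose tags
    will be collapsed onto A's coordinates by the truth SAM writer."""
    plus = [i for i, loc in enumerate(truth.loci) if loc.strand == "+"]
    order = rng.permutation(len(plus))
    pairs: list[tuple[int, int]] = []
    for k in range(0, len(order) - 1, 2):
        pairs.append((plus[order[k]], plus[order[k + 1]]))
        if len(pairs) == n_pairs:
            break
    return pairs
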