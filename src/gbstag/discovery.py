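"""SNP discovery: TagLocus grouping, de novo tag alignment, binomial
likelihood-ratio genotype calling, and population-genetic SNP filtering.

All tags that align to the same reference cut-site coordinate and strand
form a *TagLocus*.  Tags at a locus are multiple-aligned de novo (they
share an anchored cut-site start but may differ in length and carry
indels), every polymorphic alignment column becomes a SNP candidate, and
per-taxon genotypes are called from the top two allele depths by comparing
three binomial likelihoods:

    L(hom A)  = Binom(d_B | n, e)      n = d_A + d_B, e = per-base error
    L(hom B)  = Binom(d_A | n, e)
    L(het)    = Binom(d_A | n, 1/2)

The maximum-likelihood genotype wins; ties, or homozygote/heterozygote
likelihood ratios below ``lr_threshold``, resolve to the heterozygote
(the conservative call at low depth).

Filtering is population-genetic rather than quality-score based.  With
q the minor allele frequency, Ho the observed and He = 2q(1-q) the
expected heterozygosity, the inbreeding coefficient F_IT = 1 - Ho/He is
strongly negative at paralog-merged loci (excess heterozygosity), and the
inbred heterozygosity score

    nInbredHets / (nInbredsGT1ReadHomoMin + nInbredHets + 0.5)

flags error-prone sites among designated inbred samples.  When a pedigree
of expected inbreeding coefficients is supplied, only taxa with F >= minF
enter these statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqcore import Tag
from .tbt import TBT
from .topm import GAP, TOPM, AlignStatus, TOPMEntry, Variant

# Genotype codes (relative to a candidate's top-two alleles)
MISSING = -1
HOM_MAJOR = 0
HET = 1
HOM_MINOR = 2

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", GAP: GAP}


# ---------------------------------------------------------------------------
# TagLocus grouping


@dataclass
class TagLocus:
    chrom: str
    strand: str
    cut_pos: int
    tags: list[Tag]
    rows: list[int]  # TBT row index of each member tag

    def __len__(self) -> int:
        return len(self.tags)


def group_tag_loci(topm: TOPM, tbt: TBT) -> list[TagLocus]:
    """Partition UNIQUE tags by (chrom, strand, cut_pos), in position order."""
    row_of = {t: i for i, t in enumerate(tbt.tags)}
    loci: dict[tuple, TagLocus] = {}
    for e in topm.iter_by_position():
        key = (e.chrom, e.cut_pos, e.strand)
        if key not in loci:
            loci[key] = TagLocus(e.chrom, e.strand, e.cut_pos, [], [])
        loc = loci[key]
        loc.tags.append(e.tag)
        loc.rows.append(row_of[e.tag])
    return [loci[k] for k in sorted(loci)]


# ---------------------------------------------------------------------------
# Alignment: pairwise Needleman-Wunsch + progressive profile alignment

MATCH = 2
MISMATCH = -1
GAP_PENALTY = -3


def nw_align(a: str, b: str) -> tuple[int, str, str]:
    """Global alignment with anchored 5' ends and free 3'-end gaps.

    Tags at a locus start at the same cut site, so leading gaps are
    penalized normally; trailing gaps are free because tags legitimately
    differ in length.  Returns (score, gapped_a, gapped_b); traceback
    prefers diagonal over up over left for determinism.
    """
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1), dtype=np.int64)
    S[0, :] = np.arange(m + 1) * GAP_PENALTY
    S[:, 0] = np.arange(n + 1) * GAP_PENALTY
    for i in range(1, n + 1):
        ai = a[i - 1]
        prev = S[i - 1]
        cur = S[i]
        for j in range(1, m + 1):
            d = prev[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            u = prev[j] + GAP_PENALTY
            l = cur[j - 1] + GAP_PENALTY
            cur[j] = d if d >= u and d >= l else (u if u >= l else l)
    # Free end gaps: best cell on the last row/column wins.
    end_i, end_j, best = n, m, S[n, m]
    for j in range(m + 1):
        if S[n, j] > best:
            end_i, end_j, best = n, j, S[n, j]
    for i in range(n + 1):
        if S[i, m] > best:
            end_i, end_j, best = i, m, S[i, m]
    ga = [a[end_i:]] if end_i < n else []
    gb = ["-" * (n - end_i)] if end_i < n else []
    if end_j < m:
        ga = ["-" * (m - end_j)]
        gb = [b[end_j:]]
    i, j = end_i, end_j
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + GAP_PENALTY:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return int(best), "".join(reversed(ra)) + "".join(ga), "".join(reversed(rb)) + "".join(gb)


@dataclass
class TagLocusAlignment:
    """Gapped member sequences (locus member order) of equal gapped length."""

    locus: TagLocus
    rows: list[str]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ref_position(self, column: int) -> int:
        """Reference coordinate a column anchors to (cut_pos +/- column)."""
        if self.locus.strand == "+":
            return self.locus.cut_pos + column
        return self.locus.cut_pos - column


def _consensus(rows: list[str]) -> str:
    cols = []
    for c in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[c]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            cols.append(max(sorted(counts), key=lambda k: counts[k]))
        else:
            cols.append("A")  # all-gap column cannot arise; placate typing
    return "".join(cols)


def align_tag_locus(locus: TagLocus, weights: Optional[list[int]] = None) -> TagLocusAlignment:
    """Progressive MSA of a locus's tags.

    Guide order is most-frequent-first (``weights``, e.g. TBT row sums),
    tie-broken by tag order, so the alignment is deterministic.  Each new
    sequence is aligned against the running consensus; new gaps propagate
    into all previous rows (once a gap, always a gap).  For two-tag loci
    this reduces to a single optimal pairwise alignment.
    """
    seqs = [t.sequence for t in locus.tags]
    if weights is None:
        weights = [0] * len(seqs)
    order = sorted(range(len(seqs)), key=lambda i: (-weights[i], locus.tags[i]))
    aligned: list[str] = [seqs[order[0]]]
    for k in order[1:]:
        cons = _consensus(aligned)
        _score, g_cons, g_new = nw_align(cons, seqs[k])
        # Re-expand previous rows wherever the consensus gained a gap.
        merged = []
        for row in aligned:
            out = []
            it = iter(row)
            for ch in g_cons:
                out.append("-" if ch == "-" else next(it))
            merged.append("".join(out))
        merged.append(g_new)
        aligned = merged
    # Restore locus member order.
    by_member = [""] * len(seqs)
    for pos, k in enumerate(order):
        by_member[k] = aligned[pos]
    return TagLocusAlignment(locus, by_member)


# ---------------------------------------------------------------------------
# Genotype calling


def call_genotype(
    depth_major: int,
    depth_minor: int,
    err: float = 0.01,
    lr_threshold: float = 1.0,
) -> int:
    """Three-hypothesis binomial likelihood call on two allele depths.

    Returns HOM_MAJOR / HET / HOM_MINOR / MISSING codes relative to the
    (major, minor) depth arguments.  ``lr_threshold`` > 1 demands that the
    best homozygote beat the heterozygote by that likelihood ratio;
    otherwise the call falls back to the heterozygote.
    """
    if depth_major < 0 or depth_minor < 0:
        raise ValueError("allele depths must be non-negative")
    if not 0.0 < err < 0.5:
        raise ValueError("error rate must be in (0, 0.5)")
    n = depth_major + depth_minor
    if n == 0:
        return MISSING
    comb_minor = math.comb(n, depth_minor)
    l_hom_major = comb_minor * err ** depth_minor * (1.0 - err) ** depth_major
    l_hom_minor = comb_minor * err ** depth_major * (1.0 - err) ** depth_minor
    l_het = math.comb(n, depth_major) * 0.5 ** n
    if l_hom_major >= l_hom_minor:
        best_hom, hom_code = l_hom_major, HOM_MAJOR
    else:
        best_hom, hom_code = l_hom_minor, HOM_MINOR
    if l_het >= best_hom or best_hom < lr_threshold * l_het:
        return HET
    return hom_code


# ---------------------------------------------------------------------------
# SNP candidates


@dataclass
class SNPCandidate:
    chrom: str
    pos: int            # 1-based reference coordinate
    strand: str         # strand of the discovering TagLocus
    column: int         # 0-based alignment column within the locus
    alleles: list[str]  # reference-sense, ordered by depth (desc), then lexical
    depths: np.ndarray  # (n_alleles, n_taxa) summed tag depths
    calls: np.ndarray   # per-taxon genotype codes over the top two alleles
    locus_coverage: float = 0.0

    @property
    def tag_alleles(self) -> list[str]:
        """Alleles in tag orientation (as they appear in the alignment)."""
        if self.strand == "+":
            return self.alleles
        return [_COMPL[a] for a in self.alleles]


def _orient(allele: str, strand: str) -> str:
    return allele if strand == "+" else _COMPL[allele]


def discover_snps(
    alignment: TagLocusAlignment,
    tbt: TBT,
    err: float = 0.01,
    lr_threshold: float = 1.0,
) -> list[SNPCandidate]:
    """Candidates at every alignment column showing >= 2 alleles (gaps count).

    Per-taxon allele depths are the sums of the TBT depths of the member
    tags carrying that allele; genotypes are called on the top two alleles
    and taxa carrying only third-or-lower alleles stay missing.
    """
    locus = alignment.locus
    n_taxa = len(tbt.taxa)
    depth_rows = [tbt.depths[r].astype(np.int64) for r in locus.rows]
    cover = np.zeros(n_taxa, dtype=np.int64)
    for d in depth_rows:
        cover += d
    locus_coverage = float((cover > 0).sum()) / n_taxa if n_taxa else 0.0
    out: list[SNPCandidate] = []
    for c in range(alignment.width):
        chars = [row[c] for row in alignment.rows]
        present = sorted(set(chars))
        if len(present) < 2:
            continue
        depth_by_allele = {a: np.zeros(n_taxa, dtype=np.int64) for a in present}
        for ch, d in zip(chars, depth_rows):
            depth_by_allele[ch] += d
        order = sorted(present, key=lambda a: (-int(depth_by_allele[a].sum()), a))
        d0 = depth_by_allele[order[0]]
        d1 = depth_by_allele[order[1]]
        calls = np.full(n_taxa, MISSING, dtype=np.int8)
        for t in range(n_taxa):
            if d0[t] or d1[t]:
                calls[t] = call_genotype(int(d0[t]), int(d1[t]), err, lr_threshold)
        out.append(
            SNPCandidate(
                chrom=locus.chrom,
                pos=alignment.ref_position(c),
                strand=locus.strand,
                column=c,
                alleles=[_orient(a, locus.strand) for a in order],
                depths=np.vstack([depth_by_allele[a] for a in order]),
                calls=calls,
                locus_coverage=locus_coverage,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Site statistics and filters


@dataclass
class SiteStats:
    q: float                  # minor allele frequency in the scored subpopulation
    ho: float                 # observed heterozygosity
    he: float                 # expected heterozygosity 2q(1-q)
    f_it: Optional[float]     # 1 - Ho/He; None when He == 0
    inbred_coverage: Optional[float] = None
    n_inbred_hets: Optional[int] = None
    n_inbreds_gt1read_homo_min: Optional[int] = None
    inbred_het_score: Optional[float] = None
    locus_coverage: float = 0.0
    n_called: int = 0


@dataclass
class FilterConfig:
    """Thresholds of the standard Discovery Build SNP filters.

    Comparison senses follow the standard build: MAF >= min_maf,
    F_IT >= min_fit, inbred coverage > min_inbred_coverage, inbred het
    score < max_inbred_het_score, locus coverage >= min_locus_coverage.
    """

    min_maf: float = 0.001
    min_f: float = 0.8
    min_fit: float = 0.8
    min_inbred_coverage: float = 0.15
    max_inbred_het_score: float = 0.21
    min_locus_coverage: float = 0.1
    max_variants: int = 8
    err: float = 0.01
    lr_threshold: float = 1.0


PedigreeInfo = dict  # taxon name -> expected inbreeding coefficient F in [0, 1]


def inbred_mask(taxa: list[str], pedigree: Optional[PedigreeInfo], min_f: float) -> Optional[np.ndarray]:
    if pedigree is None:
        return None
    for t, f in pedigree.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"pedigree F for {t!r} outside [0, 1]")
    return np.array([pedigree.get(t, 0.0) >= min_f for t in taxa], dtype=bool)


def compute_site_stats(
    candidate: SNPCandidate,
    taxa: list[str],
    pedigree: Optional[PedigreeInfo] = None,
    min_f: float = 0.8,
) -> SiteStats:
    """MAF, heterozygosity, F_IT and the inbred-sample statistics.

    With a pedigree, q/Ho/F_IT are computed over the inbred subset
    (F >= min_f); without one, over all taxa.
    """
    mask = inbred_mask(taxa, pedigree, min_f)
    calls = candidate.calls
    sub = calls if mask is None else calls[mask]
    called = sub[sub != MISSING]
    n = len(called)
    n_hom0 = int((called == HOM_MAJOR).sum())
    n_het = int((called == HET).sum())
    n_hom1 = int((called == HOM_MINOR).sum())
    if n == 0:
        stats = SiteStats(q=float("nan"), ho=float("nan"), he=0.0, f_it=None,
                          locus_coverage=candidate.locus_coverage, n_called=0)
    else:
        p0 = (2 * n_hom0 + n_het) / (2 * n)
        q = min(p0, 1.0 - p0)
        ho = n_het / n
        he = 2.0 * q * (1.0 - q)
        f_it = 1.0 - ho / he if he > 0 else None
        stats = SiteStats(q=q, ho=ho, he=he, f_it=f_it,
                          locus_coverage=candidate.locus_coverage, n_called=n)
    if mask is not None:
        n_inbred = int(mask.sum())
        stats.inbred_coverage = n / n_inbred if n_inbred else 0.0
        stats.n_inbred_hets = n_het
        # hom-minor means homozygous for the genotype-frequency minor allele
        if n > 0 and (2 * n_hom0 + n_het) / (2 * n) < 0.5:
            minor_code = HOM_MAJOR
        else:
            minor_code = HOM_MINOR
        site_depth = candidate.depths[:2].sum(axis=0)
        deep = (site_depth > 1) if mask is None else (site_depth[mask] > 1)
        stats.n_inbreds_gt1read_homo_min = int(((sub == minor_code) & deep).sum())
        stats.inbred_het_score = stats.n_inbred_hets / (
            stats.n_inbreds_gt1read_homo_min + stats.n_inbred_hets + 0.5
        )
    return stats


def passes_filters(stats: SiteStats, cfg: FilterConfig, has_pedigree: bool) -> bool:
    """Retention rule; monomorphic sites (He == 0) always fail."""
    if stats.n_called == 0 or math.isnan(stats.q):
        return False
    if stats.locus_coverage < cfg.min_locus_coverage:
        return False
    if stats.q < cfg.min_maf:
        return False
    if stats.f_it is None or stats.f_it < cfg.min_fit:
        return False
    if has_pedigree:
        if stats.inbred_coverage is None or not stats.inbred_coverage > cfg.min_inbred_coverage:
            return False
        if stats.inbred_het_score is None or not stats.inbred_het_score < cfg.max_inbred_het_score:
            return False
    return True


def filter_snps(
    candidates: list[SNPCandidate],
    stats: list[SiteStats],
    cfg: FilterConfig,
    has_pedigree: bool,
) -> list[int]:
    """Indices of retained candidates."""
    return [
        i for i, (c, s) in enumerate(zip(candidates, stats))
        if passes_filters(s, cfg, has_pedigree)
    ]


# ---------------------------------------------------------------------------
# Full Discovery run


@dataclass
class LocusResult:
    locus: TagLocus
    alignment: TagLocusAlignment
    candidates: list[SNPCandidate]
    stats: list[SiteStats]
    retained: list[int]


@dataclass
class DiscoveryReport:
    loci: list[LocusResult] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return sum(len(lr.candidates) for lr in self.loci)

    @property
    def n_retained(self) -> int:
        return sum(len(lr.retained) for lr in self.loci)

    def retained_candidates(self) -> list[tuple[SNPCandidate, SiteStats]]:
        out = []
        for lr in self.loci:
            for i in lr.retained:
                out.append((lr.candidates[i], lr.stats[i]))
        out.sort(key=lambda cs: (cs[0].chrom, cs[0].pos, cs[0].strand))
        return out


def run_discovery(
    topm: TOPM,
    tbt: TBT,
    pedigree: Optional[PedigreeInfo] = None,
    cfg: Optional[FilterConfig] = None,
) -> tuple[TOPM, DiscoveryReport]:
    """Run the full Discovery stage and write retained variants into a
    production-ready copy of the TOPM.

    Each member tag of a locus receives one (alignment column, allele)
    variant per retained SNP at that locus, capped at ``cfg.max_variants``
    per tag (earliest columns win).
    """
    if cfg is None:
        cfg = FilterConfig()
    has_pedigree = pedigree is not None
    out = topm.copy()
    out.max_variants = cfg.max_variants
    report = DiscoveryReport(taxa=list(tbt.taxa))
    for locus in group_tag_loci(topm, tbt):
        weights = [int(tbt.depths[r].sum()) for r in locus.rows]
        alignment = align_tag_locus(locus, weights)
        candidates = discover_snps(alignment, tbt, err=cfg.err, lr_threshold=cfg.lr_threshold)
        stats = [compute_site_stats(c, tbt.taxa, pedigree, cfg.min_f) for c in candidates]
        retained = filter_snps(candidates, stats, cfg, has_pedigree)
        report.loci.append(LocusResult(locus, alignment, candidates, stats, retained))
        if retained:
            columns = sorted(candidates[i].column for i in retained)[: cfg.max_variants]
            for tag, row in zip(locus.tags, alignment.rows):
                out.annotate_variants(tag, [Variant(c, row[c]) for c in columns])
    return out, report
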