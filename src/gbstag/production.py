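"""Production genotyping: one-step calling of new FASTQ files against a
production-ready TOPM, with replicate tallying and HapMap/VCF output.

Once Discovery has annotated variants into the TOPM, genotyping new
samples is a single pass: classify each read, match its tag exactly
(sequence + length, after the identical trimming rules) against the
annotated tags, add the tag's variant alleles to the taxon's allele
depths, tally replicates of the same sample across lanes, and call
genotypes with the same binomial likelihood-ratio caller used in
Discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seqcore import (
    DEFAULT_MIN_TAG_LENGTH,
    MAX_TAG_LENGTH,
    BarcodeKey,
    EnzymeModel,
    LaneClassifier,
    ReadStatus,
    iter_fastq,
    _open_text,
)
from .discovery import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    DiscoveryReport,
    _orient,
    call_genotype,
)
from .topm import GAP, TOPM

DEPTH_CAP = 127

_IUPAC_HET = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int
    alleles: tuple[str, ...]  # reference-sense, major first


@dataclass
class GenotypeTable:
    """Taxa x sites genotype calls plus per-site allele depths.

    ``calls[s, t]`` is a code over site s's top-two alleles
    (HOM_MAJOR/HET/HOM_MINOR/MISSING); ``depths[s]`` is an
    (n_alleles, n_taxa) array.  Sites are sorted by (chrom, pos).
    """

    taxa: list[str]
    sites: list[Site]
    calls: np.ndarray
    depths: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        order = sorted(range(len(self.sites)), key=lambda i: (self.sites[i].chrom, self.sites[i].pos))
        if order != list(range(len(self.sites))):
            self.sites = [self.sites[i] for i in order]
            self.calls = self.calls[order]
            if self.depths:
                self.depths = [self.depths[i] for i in order]

    def genotype_alleles(self, s: int, t: int) -> Optional[tuple[str, str]]:
        """The unordered allele pair called for taxon t at site s."""
        code = int(self.calls[s, t])
        a = self.sites[s].alleles
        if code == MISSING:
            return None
        if code == HOM_MAJOR:
            return (a[0], a[0])
        if code == HOM_MINOR:
            return (a[1], a[1])
        return tuple(sorted((a[0], a[1])))

    def same_genotypes(self, other: "GenotypeTable") -> bool:
        if self.taxa != other.taxa or self.sites != other.sites:
            return False
        return bool(np.array_equal(self.calls, other.calls))


def genotype_table_from_discovery(report: DiscoveryReport) -> GenotypeTable:
    """Assemble the Discovery stage's retained SNP calls into a table.

    A position discovered from both strands keeps the deeper call set
    (deterministic tie-break by strand), so the table has one row per
    (chrom, pos).
    """
    best: dict[tuple[str, int], tuple] = {}
    for cand, _stats in report.retained_candidates():
        key = (cand.chrom, cand.pos)
        depth = int(cand.depths.sum())
        prior = best.get(key)
        if prior is None or (depth, cand.strand) > (prior[0], prior[1]):
            best[key] = (depth, cand.strand, cand)
    sites, calls, depths = [], [], []
    for key in sorted(best):
        cand = best[key][2]
        sites.append(Site(cand.chrom, cand.pos, tuple(cand.alleles[:2])))
        calls.append(cand.calls)
        depths.append(cand.depths[:2])
    n_taxa = len(report.taxa)
    call_mat = np.vstack(calls) if calls else np.zeros((0, n_taxa), dtype=np.int8)
    return GenotypeTable(list(report.taxa), sites, call_mat, depths)


def genotypes_equal(a: GenotypeTable, b: GenotypeTable, taxa: Optional[list[str]] = None) -> bool:
    """True iff both tables call the same unordered allele pair for every
    taxon at every site (sites matched by chrom/pos; allele ordering and
    depth bookkeeping may differ)."""
    sa = {(s.chrom, s.pos): i for i, s in enumerate(a.sites)}
    sb = {(s.chrom, s.pos): i for i, s in enumerate(b.sites)}
    if set(sa) != set(sb):
        return False
    if taxa is None:
        if a.taxa != b.taxa:
            return False
        pairs = [(t, t) for t in range(len(a.taxa))]
    else:
        pairs = [(a.taxa.index(t), b.taxa.index(t)) for t in taxa]
    for key, i in sa.items():
        j = sb[key]
        for ta, tb in pairs:
            if a.genotype_alleles(i, ta) != b.genotype_alleles(j, tb):
                return False
    return True


# ---------------------------------------------------------------------------
# Production run


@dataclass
class ProductionReport:
    total_reads: int = 0
    good_reads: int = 0
    matched_reads: int = 0
    unmatched_good: int = 0
    rejected: dict[str, int] = field(default_factory=dict)


def run_production(
    fastqs: list[tuple[object, str, str]],
    key: BarcodeKey,
    topm_prod: TOPM,
    enzyme: EnzymeModel,
    trim_length: int = MAX_TAG_LENGTH,
    min_tag_length: int = DEFAULT_MIN_TAG_LENGTH,
    require_remnant: bool = True,
    err: float = 0.01,
    lr_threshold: float = 1.0,
) -> tuple[GenotypeTable, ProductionReport]:
    """Genotype (fastq, flowcell, lane) inputs against an annotated TOPM.

    Replicate lanes of the same taxon tally into one column before
    calling.  Matching is exact on (sequence, length): the trimmed read is
    truncated to each candidate tag's length and compared, via an index on
    the tags' leading 32-base prefix.
    """
    annotated = topm_prod.annotated_entries()
    if not annotated:
        raise ValueError("production-ready TOPM has no variant-annotated tags")

    exact = {}
    prefix_index: dict[str, list] = {}
    for e in annotated:
        seq = e.tag.sequence
        exact[seq] = e
        prefix_index.setdefault(seq[:32], []).append((e.tag.length, seq, e))
    for cands in prefix_index.values():
        cands.sort(reverse=True)  # longest candidate tag wins, deterministically

    # Site registry: (chrom, pos) -> tag-sense alleles seen in the TOPM.
    site_alleles: dict[tuple[str, int, str], set] = {}
    for e in annotated:
        for v in e.variants:
            pos = e.cut_pos + v.offset if e.strand == "+" else e.cut_pos - v.offset
            site_alleles.setdefault((e.chrom, pos, e.strand), set()).add(v.allele)

    taxa = key.taxa
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    # (chrom,pos,strand) -> {tag-sense allele -> depth vector}
    tallies: dict[tuple, dict[str, np.ndarray]] = {
        k: {a: np.zeros(len(taxa), dtype=np.int64) for a in alleles}
        for k, alleles in site_alleles.items()
    }
    report = ProductionReport()
    for fastq, flowcell, lane in sorted(fastqs, key=lambda x: str(x[0])):
        clf = LaneClassifier(
            key.lane_entries(flowcell, lane), enzyme,
            trim_length=trim_length, min_tag_length=min_tag_length,
            require_remnant=require_remnant,
        )
        for _rid, seq in iter_fastq(fastq):
            c = clf.classify(seq)
            report.total_reads += 1
            if c.status is not ReadStatus.GOOD:
                report.rejected[c.status.value] = report.rejected.get(c.status.value, 0) + 1
                continue
            report.good_reads += 1
            read_seq = c.tag.sequence
            entry = exact.get(read_seq)
            if entry is None:
                for length, tseq, e in prefix_index.get(read_seq[:32], ()):
                    if length <= len(read_seq) and read_seq[:length] == tseq:
                        entry = e
                        break
            if entry is None:
                report.unmatched_good += 1
                continue
            report.matched_reads += 1
            t = taxon_idx[c.taxon]
            for v in entry.variants:
                pos = entry.cut_pos + v.offset if entry.strand == "+" else entry.cut_pos - v.offset
                tallies[(entry.chrom, pos, entry.strand)][v.allele][t] += 1

    # Merge +/- strand tallies at the same reference position into
    # reference-sense alleles, then call genotypes.
    merged: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for (chrom, pos, strand), by_allele in tallies.items():
        dest = merged.setdefault((chrom, pos), {})
        for allele, vec in by_allele.items():
            ref_allele = _orient(allele, strand)
            dest[ref_allele] = dest.get(ref_allele, np.zeros(len(taxa), dtype=np.int64)) + vec

    sites, calls, depths = [], [], []
    for (chrom, pos) in sorted(merged):
        by_allele = merged[(chrom, pos)]
        capped = {a: np.minimum(v, DEPTH_CAP) for a, v in by_allele.items()}
        order = sorted(capped, key=lambda a: (-int(capped[a].sum()), a))
        if len(order) < 2:
            continue  # depth bookkeeping only; no segregating alleles observed
        d = np.vstack([capped[a] for a in order])
        site_calls = np.full(len(taxa), MISSING, dtype=np.int8)
        for t in range(len(taxa)):
            if d[0, t] or d[1, t]:
                site_calls[t] = call_genotype(int(d[0, t]), int(d[1, t]), err, lr_threshold)
        sites.append(Site(chrom, pos, tuple(order)))
        calls.append(site_calls)
        depths.append(d[:2])
    call_mat = np.vstack(calls) if calls else np.zeros((0, len(taxa)), dtype=np.int8)
    return GenotypeTable(taxa, sites, call_mat, depths), report


# ---------------------------------------------------------------------------
# HapMap output

_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def _hapmap_symbol(site: Site, code: int) -> str:
    a0, a1 = site.alleles[0], site.alleles[1]
    indel = GAP in (a0, a1)
    if code == MISSING:
        return "N"
    if indel:
        # '+' = the base allele, '-' = the gap allele, '0' = heterozygous
        if code == HET:
            return "0"
        allele = a0 if code == HOM_MAJOR else a1
        return "-" if allele == GAP else "+"
    if code == HOM_MAJOR:
        return a0
    if code == HOM_MINOR:
        return a1
    return _IUPAC_HET[frozenset((a0, a1))]


def write_hapmap(gt: GenotypeTable, path) -> None:
    if not gt.sites:
        raise ValueError("refusing to write an empty genotype table")
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_HAPMAP_HEADER + gt.taxa) + "\n")
        for s, site in enumerate(gt.sites):
            a0, a1 = site.alleles[0], site.alleles[1]
            name = f"S{site.chrom}_{site.pos}"
            row = [
                name, f"{a0}/{a1}", site.chrom, str(site.pos), "+",
                "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            row += [_hapmap_symbol(site, int(gt.calls[s, t])) for t in range(len(gt.taxa))]
            fh.write("\t".join(row) + "\n")


_IUPAC_REV = {v: tuple(sorted(k)) for k, v in _IUPAC_HET.items()}


def read_hapmap(path) -> GenotypeTable:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        taxa = header[len(_HAPMAP_HEADER):]
        sites, calls = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            alleles = tuple(parts[1].split("/"))
            site = Site(parts[2], int(parts[3]), alleles)
            sites.append(site)
            a0, a1 = alleles
            indel = GAP in alleles
            row = []
            for sym in parts[len(_HAPMAP_HEADER):]:
                if sym == "N":
                    row.append(MISSING)
                elif indel:
                    if sym == "0":
                        row.append(HET)
                    elif sym == "-":
                        row.append(HOM_MAJOR if a0 == GAP else HOM_MINOR)
                    else:
                        row.append(HOM_MAJOR if a0 != GAP else HOM_MINOR)
                elif sym == a0:
                    row.append(HOM_MAJOR)
                elif sym == a1:
                    row.append(HOM_MINOR)
                else:
                    row.append(HET)
            calls.append(np.array(row, dtype=np.int8))
    mat = np.vstack(calls) if calls else np.zeros((0, len(taxa)), dtype=np.int8)
    return GenotypeTable(taxa, sites, mat)


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(gt: GenotypeTable, path, reference: Optional[dict[str, str]] = None) -> None:
    """VCF 4.2 with GT and AD per sample.

    The REF allele is the reference base when a reference is supplied and
    consistent with the site's alleles, else the major allele (noted in
    the header).  Gap alleles become anchored indels at pos-1.
    """
    if not gt.sites:
        raise ValueError("refusing to write an empty genotype table")
    ref_based = reference is not None
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"##REF_policy={'reference base' if ref_based else 'major allele'}\n")
        chroms = sorted({s.chrom for s in gt.sites})
        for c in chroms:
            length = len(reference[c]) if ref_based and c in reference else 2**29
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gt.taxa) + "\n")
        for s, site in enumerate(gt.sites):
            a0, a1 = site.alleles[0], site.alleles[1]
            if GAP in (a0, a1):
                base = a1 if a0 == GAP else a0
                anchor = "N"
                pos = site.pos - 1
                if ref_based and site.chrom in reference and pos >= 1:
                    anchor = reference[site.chrom][pos - 1]
                ref_a, alt_a = anchor + base, anchor
                swap = a0 == GAP  # major allele is the deletion
            else:
                pos = site.pos
                if ref_based and site.chrom in reference:
                    refbase = reference[site.chrom][site.pos - 1]
                else:
                    refbase = a0
                swap = refbase == a1
                ref_a, alt_a = (a1, a0) if swap else (a0, a1)
            fields = [site.chrom, str(pos), f"S{site.chrom}_{site.pos}", ref_a, alt_a,
                      ".", "PASS", ".", "GT:AD"]
            for t in range(len(gt.taxa)):
                code = int(gt.calls[s, t])
                d = gt.depths[s][:, t] if gt.depths else np.array([0, 0])
                ad = (int(d[1]), int(d[0])) if swap else (int(d[0]), int(d[1]))
                if code == MISSING:
                    g = "./."
                elif code == HET:
                    g = "0/1"
                elif (code == HOM_MAJOR) != swap:
                    g = "0/0"
                else:
                    g = "1/1"
                fields.append(f"{g}:{ad[0]},{ad[1]}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeTable:
    """Read back a VCF written by :func:`write_vcf` (uses pysam)."""
    import pysam

    sites, calls, depths = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        taxa = list(vf.header.samples)
        for rec in vf:
            ref_a, alt_a = rec.ref, rec.alts[0]
            if len(ref_a) != len(alt_a):  # anchored indel
                pos = rec.pos + 1
                base = ref_a[1:] if len(ref_a) > len(alt_a) else alt_a[1:]
                pair = (base, GAP) if len(ref_a) > len(alt_a) else (GAP, base)
                site_alleles = pair
            else:
                pos = rec.pos
                site_alleles = (ref_a, alt_a)
            row, drow = [], []
            for t in taxa:
                smp = rec.samples[t]
                gtv = smp["GT"]
                ad = smp.get("AD", (0, 0))
                drow.append((int(ad[0] or 0), int(ad[1] or 0)))
                if gtv is None or gtv[0] is None:
                    row.append(MISSING)
                elif gtv[0] != gtv[1]:
                    row.append(HET)
                elif gtv[0] == 0:
                    row.append(HOM_MAJOR)
                else:
                    row.append(HOM_MINOR)
            # Restore major-first allele ordering by total depth.
            tot0 = sum(d[0] for d in drow)
            tot1 = sum(d[1] for d in drow)
            swap = (tot1, site_alleles[0]) > (tot0, site_alleles[1])
            if swap:
                site_alleles = (site_alleles[1], site_alleles[0])
                row = [HOM_MAJOR if c == HOM_MINOR else HOM_MINOR if c == HOM_MAJOR else c for c in row]
                drow = [(d1, d0) for d0, d1 in drow]
            sites.append(Site(rec.chrom, pos, site_alleles))
            calls.append(np.array(row, dtype=np.int8))
            depths.append(np.array(drow, dtype=np.int64).T)
    mat = np.vstack(calls) if calls else np.zeros((0, len(taxa)), dtype=np.int8)
    return GenotypeTable(taxa, sites, mat, depths)
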