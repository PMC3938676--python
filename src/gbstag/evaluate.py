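"""Truth-table evaluation helpers for synthetic runs.

Given a :class:`~gbstag.simdata.TruthSet` these compare pipeline output
against the simulated truth: which true SNPs were discoverable from the
master tag list, and how often called genotypes match the truth
genotypes.
"""

from __future__ import annotations

import numpy as np

from .production import GenotypeTable
from .simdata import G_HET, G_HOM_ALT, G_HOM_REF, TruthSet
from .tagcounts import MasterTagList

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def discoverable_snps(truth: TruthSet, master: MasterTagList) -> set[tuple[str, int]]:
    """True SNP positions whose both alleles survive in the master tag list.

    A SNP is only discoverable if tags carrying each of its alleles passed
    the experiment-wide minimum tag count; alleles whose tag evidence fell
    below that threshold are, by construction, invisible to Discovery.
    Intended for error-free runs (error tags would contribute fake alleles).
    """
    alleles_seen: dict[int, set[str]] = {}
    for tag in master.tags():
        seq = tag.sequence
        for li in truth.tag_origin.get(seq, ()):
            loc = truth.loci[li]
            for sid in loc.snp_ids:
                snp = truth.snps[sid]
                if loc.strand == "+":
                    off = snp.pos - 1 - loc.start0
                    if off < len(seq):
                        alleles_seen.setdefault(sid, set()).add(seq[off])
                else:
                    off = loc.end0 - snp.pos
                    if off < len(seq):
                        alleles_seen.setdefault(sid, set()).add(_COMPL[seq[off]])
    return {
        (truth.snps[sid].chrom, truth.snps[sid].pos)
        for sid, alleles in alleles_seen.items()
        if len(alleles) >= 2
    }


def truth_genotype_pair(truth: TruthSet, snp_idx: int, taxon_idx: int) -> tuple[str, str]:
    s = truth.snps[snp_idx]
    g = int(truth.genotypes[snp_idx, taxon_idx])
    if g == G_HOM_REF:
        return (s.ref_allele, s.ref_allele)
    if g == G_HOM_ALT:
        return (s.alt_allele, s.alt_allele)
    return tuple(sorted((s.ref_allele, s.alt_allele)))


def genotype_concordance(gt: GenotypeTable, truth: TruthSet) -> tuple[int, int]:
    """(n_matching, n_compared) over non-missing calls at sites that
    coincide with true SNP positions."""
    snp_by_pos = {(s.chrom, s.pos): j for j, s in enumerate(truth.snps)}
    taxon_idx = {t: i for i, t in enumerate(truth.taxa)}
    cols = [taxon_idx[t] for t in gt.taxa]
    match = total = 0
    for i, site in enumerate(gt.sites):
        j = snp_by_pos.get((site.chrom, site.pos))
        if j is None:
            continue
        for t in range(len(gt.taxa)):
            pair = gt.genotype_alleles(i, t)
            if pair is None:
                continue
            total += 1
            if tuple(sorted(pair)) == truth_genotype_pair(truth, j, cols[t]):
                match += 1
    return match, total


def genotype_error_rate(gt: GenotypeTable, truth: TruthSet) -> float:
    match, total = genotype_concordance(gt, truth)
    return (total - match) / total if total else float("nan")
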