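"""Per-SNP genotyping error rates from biparental RIL families.

In an F2-derived recombinant-inbred-line (RIL) family a real SNP either
does not segregate (both parents carried the same allele) or segregates
near 1:1.  A family in which a SNP's minor allele frequency is above zero
but well below the segregating range, while the allele counts deviate
significantly from 1:1 (exact binomial test), exposes those minor-allele
calls as genotyping errors.  The per-SNP error rate is the total number of
such error calls divided by the total number of calls in families where
the SNP deviates from 1:1 (monomorphic families included: MAF 0 trivially
deviates, and an error-free monomorphic family contributes error-free
calls to the denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .discovery import HET, HOM_MAJOR, HOM_MINOR, MISSING
from .production import GenotypeTable
from .seqcore import _open_text

FamilyAssignment = dict  # taxon name -> family identifier


def binomial_segregation_test(n_minor: int, n: int) -> float:
    """Exact two-sided binomial p-value against proportion 0.5.

    Computed as min(1, 2 x smaller one-tailed tail probability).
    """
    if n < 1 or not 0 <= n_minor <= n:
        raise ValueError(f"invalid counts ({n_minor}, {n})")
    lower = binom.cdf(n_minor, n, 0.5)
    upper = binom.sf(n_minor - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class ErrorRateReport:
    per_snp: pd.DataFrame
    per_family_segregating: dict[str, int] = field(default_factory=dict)

    @property
    def mean_error_rate(self) -> float:
        rates = self.per_snp["error_rate"].dropna()
        return float(rates.mean()) if len(rates) else float("nan")

    @property
    def median_error_rate(self) -> float:
        rates = self.per_snp["error_rate"].dropna()
        return float(rates.median()) if len(rates) else float("nan")

    @property
    def pooled_error_rate(self) -> float:
        """Total error calls over total denominator calls, across SNPs."""
        denom = self.per_snp["n_total_calls_deviating"].sum()
        return float(self.per_snp["n_error_calls"].sum() / denom) if denom else float("nan")


def parse_family_file(path) -> FamilyAssignment:
    """Tab-delimited file with Taxon and Family columns."""
    fam: FamilyAssignment = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        if "Taxon" not in idx or "Family" not in idx:
            raise ValueError("family file needs Taxon and Family columns")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fam[parts[idx["Taxon"]]] = parts[idx["Family"]]
    return fam


def estimate_error_rates(
    gt: GenotypeTable,
    fam: FamilyAssignment,
    min_n: int = 19,
    maf_upper: float = 0.25,
    alpha: float = 0.001,
) -> ErrorRateReport:
    """Per-SNP error rates over SNP x family combinations with
    n >= ``min_n`` non-missing calls.

    Family MAF is computed from allele counts with heterozygotes counting
    half toward each allele.  A family's minor-allele calls are errors iff
    0 < MAF < ``maf_upper`` and the family deviates from 1:1 at
    p < ``alpha``; the denominator pools all calls in deviating families
    (monomorphic families included by rule).  Families with MAF in
    [``maf_upper``, 0.75] count as properly segregating.
    """
    for taxon in fam:
        if taxon not in gt.taxa:
            raise KeyError(f"family-assigned taxon {taxon!r} absent from genotype table")
    families: dict[str, list[int]] = {}
    for i, t in enumerate(gt.taxa):
        if t in fam:
            families.setdefault(fam[t], []).append(i)

    rows = []
    seg_counts = {f: 0 for f in families}
    any_qualifying = False
    for s, site in enumerate(gt.sites):
        calls = gt.calls[s]
        n_families = 0
        n_err = 0
        n_denom = 0
        for fname, cols in sorted(families.items()):
            sub = calls[cols]
            called = sub[sub != MISSING]
            n = len(called)
            if n < min_n:
                continue
            n_families += 1
            any_qualifying = True
            n_het = int((called == HET).sum())
            n_hom0 = int((called == HOM_MAJOR).sum())
            n_hom1 = int((called == HOM_MINOR).sum())
            # The rarer homozygote class defines the family minor allele;
            # heterozygotes count half toward each allele.
            n_hom_min = min(n_hom0, n_hom1)
            minor_half = n_hom_min + 0.5 * n_het
            minor_calls = n_hom_min + n_het
            maf = minor_half / n
            if maf >= maf_upper:
                seg_counts[fname] += 1
            k = math.floor(minor_half + 0.5)  # nearest-integer minor count
            p = binomial_segregation_test(min(k, n), n)
            deviating = maf == 0.0 or p < alpha
            if deviating:
                n_denom += n
                if 0.0 < maf < maf_upper and p < alpha:
                    n_err += minor_calls
        rate = n_err / n_denom if n_denom else float("nan")
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "n_families_tested": n_families,
                "n_error_calls": n_err,
                "n_total_calls_deviating": n_denom,
                "error_rate": rate,
            }
        )
    if not any_qualifying:
        raise ValueError(f"no SNP x family combination reaches n >= {min_n}")
    return ErrorRateReport(pd.DataFrame(rows), seg_counts)


def write_error_report(report: ErrorRateReport, path) -> None:
    with _open_text(path, "wt") as fh:
        report.per_snp.to_csv(fh, sep="\t", index=False)
        fh.write(f"# mean_error_rate\t{report.mean_error_rate:.6g}\n")
        fh.write(f"# median_error_rate\t{report.median_error_rate:.6g}\n")
        for fname, n in sorted(report.per_family_segregating.items()):
            fh.write(f"# segregating_snps\t{fname}\t{n}\n")
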