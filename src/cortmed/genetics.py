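"""Gene risk score, Hardy-Weinberg check, and VCF genotype parsing.

The gene risk score (GRS) counts hypothesized risk alleles across the two
BDNF variants: rs6265 Met carriage and rs7124442 C carriage each contribute
one point, so GRS ranges 0-2.  Genotypes arrive either as carrier-class
columns in the subjects table or as a minimal two-record VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GeneRiskScore", "compute_grs", "hwe_test", "parse_vcf_genotypes",
           "MissingGenotypeError"]

RS6265_CATEGORIES = ("Val/Val", "Met-carrier")
RS7124442_CATEGORIES = ("T/T", "C-carrier")


class MissingGenotypeError(ValueError):
    """Subject lacks a genotype call and must be excluded."""


@dataclass(frozen=True)
class GeneRiskScore:
    grs: int
    met_carrier: bool
    c_carrier: bool


def compute_grs(rs6265: str, rs7124442: str) -> GeneRiskScore:
    """Risk-allele count: rs6265 Met carrier + rs7124442 C carrier."""
    if rs6265 is None or rs7124442 is None or rs6265 == "" or rs7124442 == "":
        raise MissingGenotypeError("missing genotype; subject excluded")
    if rs6265 not in RS6265_CATEGORIES:
        raise ValueError(f"unknown rs6265 category {rs6265!r}")
    if rs7124442 not in RS7124442_CATEGORIES:
        raise ValueError(f"unknown rs7124442 category {rs7124442!r}")
    met = rs6265 == "Met-carrier"
    c = rs7124442 == "C-carrier"
    return GeneRiskScore(grs=int(met) + int(c), met_carrier=met, c_carrier=c)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts come from the allele frequency estimated from the observed
    genotype counts (AA, Aa, aa).  Monomorphic samples give chi2 = 0.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)  # freq of the A allele
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    keep = expected > 0
    chi2 = float(np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep]))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def parse_vcf_genotypes(vcf_path, ref_is_major: bool = True) -> dict:
    """Read rs6265 and rs7124442 carrier classes from a VCF.

    The REF/ALT orientation must be declared: with ``ref_is_major`` (the
    convention the synthetic writer uses) REF is the Val allele at rs6265 and
    the T allele at rs7124442, so any ALT dosage > 0 marks a carrier.  Missing
    GT gives None for that subject.

    Returns {"rs6265": {sample: category|None}, "rs7124442": {...}}.
    """
    from cyvcf2 import VCF

    if not ref_is_major:
        raise ValueError(
            "only the REF=major orientation is supported; re-orient the VCF"
        )
    wanted = {
        "rs6265": RS6265_CATEGORIES,
        "rs7124442": RS7124442_CATEGORIES,
    }
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    out: dict = {}
    for rec in vcf:
        if rec.ID not in wanted:
            continue
        homref, carrier = wanted[rec.ID]
        calls = {}
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt in zip(samples, rec.gt_types):
            if gt == 2:
                calls[sample] = None
            elif gt == 0:
                calls[sample] = homref
            else:
                calls[sample] = carrier
        out[rec.ID] = calls
    missing_sites = set(wanted) - set(out)
    if missing_sites:
        raise ValueError(f"VCF lacks required records: {sorted(missing_sites)}")
    return out
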