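"""Single-locus segregation-distortion tests for F2 and NR-BC cohorts.

The F2 scan compares each marker's genotype counts to the Mendelian
2:1:1 (HET : HOM_P1 : HOM_P2) expectation with a Pearson chi-square
goodness-of-fit test (df = 2); the non-recombinant backcross is tested
per chromosome against a 1:1 HET : HOM_P2 ratio (df = 1).  A pooled
allele-ratio test asks whether P1 and P2 alleles occur in the expected
1:1 ratio over all markers and individuals.  Significance is tiered
p < 0.05, p < 0.01, and a scan-wide Bonferroni threshold, mirroring the
three-star convention of marker-scan figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .genotypes import Cohort, Genotype, GenotypeCounts, GenotypeMatrix, genotype_counts

__all__ = [
    "DistortionResult",
    "DistortionScan",
    "AlleleRatioResult",
    "f2_distortion_test",
    "scan_f2",
    "allele_ratio_test",
    "nrbc_chromosome_test",
    "scan_nrbc",
    "nrbc_chromosome_states",
]

TIERS = ("ns", "p05", "p01", "bonferroni")


def _tier(p: float, bonferroni_threshold: float | None) -> str:
    if bonferroni_threshold is not None and p < bonferroni_threshold:
        return "bonferroni"
    if p < 0.01:
        return "p01"
    if p < 0.05:
        return "p05"
    return "ns"


def _directions(observed: np.ndarray, expected: np.ndarray, labels: list[str]) -> tuple[str, ...]:
    flags = []
    for obs, exp, label in zip(observed, expected, labels):
        if obs > exp:
            flags.append(f"{label}_excess")
        elif obs < exp:
            flags.append(f"{label}_deficit")
    return tuple(flags)


@dataclass
class DistortionResult:
    marker: str
    cohort: str
    counts: GenotypeCounts
    expected: tuple[float, ...]
    chi2: float
    df: int
    p: float
    tier: str
    direction: tuple[str, ...]


@dataclass
class DistortionScan:
    """Per-marker (or per-chromosome) results plus scan-wide summary."""

    results: list[DistortionResult]
    bonferroni_threshold: float

    @property
    def fraction_p05(self) -> float:
        return float(np.mean([r.p < 0.05 for r in self.results]))

    @property
    def n_bonferroni(self) -> int:
        return sum(r.p < self.bonferroni_threshold for r in self.results)

    def summary(self) -> dict:
        return {
            "n_tests": len(self.results),
            "fraction_p05": self.fraction_p05,
            "bonferroni_threshold": self.bonferroni_threshold,
            "n_bonferroni": self.n_bonferroni,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [r.marker for r in self.results],
                "cohort": [r.cohort for r in self.results],
                "n_het": [r.counts.n_het for r in self.results],
                "n_hom_p1": [r.counts.n_hom_p1 for r in self.results],
                "n_hom_p2": [r.counts.n_hom_p2 for r in self.results],
                "n_missing": [r.counts.n_missing for r in self.results],
                "expected": [";".join(f"{e:g}" for e in r.expected) for r in self.results],
                "chi2": [r.chi2 for r in self.results],
                "df": [r.df for r in self.results],
                "p": [r.p for r in self.results],
                "tier": [r.tier for r in self.results],
                "direction": [";".join(r.direction) for r in self.results],
            }
        )


def f2_distortion_test(
    counts: GenotypeCounts,
    marker: str = "",
    cohort: str = "",
    bonferroni_threshold: float | None = None,
) -> DistortionResult:
    """Pearson chi-square test of one marker against the 2:1:1 F2 ratio.

    Observed (HET, HOM_P1, HOM_P2) counts are compared with
    (0.5, 0.25, 0.25) x n over the marker's non-missing calls; df = 2.
    Direction flags record the sign of each class deviation.
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError("no non-missing calls for this marker")
    observed = np.array([counts.n_het, counts.n_hom_p1, counts.n_hom_p2], dtype=float)
    expected = np.array([0.5, 0.25, 0.25]) * n
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(_chi2.sf(chi2, df=2))
    return DistortionResult(
        marker=marker,
        cohort=cohort,
        counts=counts,
        expected=tuple(expected),
        chi2=chi2,
        df=2,
        p=p,
        tier=_tier(p, bonferroni_threshold),
        direction=_directions(observed, expected, ["het", "hom_p1", "hom_p2"]),
    )


def scan_f2(gm: GenotypeMatrix, cohort: Cohort | str) -> DistortionScan:
    """Single-locus distortion scan over every marker of one F2 cohort.

    The Bonferroni threshold is 0.05 / (number of markers tested); each
    marker uses its own non-missing sample size.
    """
    cohort = Cohort(cohort)
    threshold = 0.05 / len(gm.markers)
    results = [
        f2_distortion_test(
            genotype_counts(gm, name, cohort),
            marker=name,
            cohort=cohort.value,
            bonferroni_threshold=threshold,
        )
        for name in gm.marker_names
    ]
    return DistortionScan(results, threshold)


@dataclass
class AlleleRatioResult:
    """Pooled test of P1 vs P2 allele counts against a 1:1 ratio."""

    n_p1_alleles: int
    n_p2_alleles: int
    chi2: float
    p: float
    direction: str  # p1_excess | p2_excess | balanced


def allele_ratio_test(gm: GenotypeMatrix, cohort: Cohort | str) -> AlleleRatioResult:
    """Genome-wide allele-ratio chi-square (df = 1) for one cohort.

    Every non-missing call contributes two alleles: heterozygotes one
    of each, homozygotes two of one type.  The test pools alleles over
    all markers and individuals, ignoring non-independence of linked
    markers (a deliberate property of the pooled statistic).
    """
    mask = gm.cohort_mask(cohort)
    calls = gm.calls[mask]
    n_het = int((calls == Genotype.HET).sum())
    n_hom_p1 = int((calls == Genotype.HOM_P1).sum())
    n_hom_p2 = int((calls == Genotype.HOM_P2).sum())
    n_p1 = 2 * n_hom_p1 + n_het
    n_p2 = 2 * n_hom_p2 + n_het
    total = n_p1 + n_p2
    if total == 0:
        raise ValueError("no non-missing calls in cohort")
    chi2 = (n_p1 - n_p2) ** 2 / total
    p = float(_chi2.sf(chi2, df=1))
    direction = (
        "balanced" if n_p1 == n_p2 else ("p1_excess" if n_p1 > n_p2 else "p2_excess")
    )
    return AlleleRatioResult(n_p1, n_p2, float(chi2), p, direction)


def nrbc_chromosome_test(
    n_het: int,
    n_hom_p2: int,
    chromosome: str = "",
    bonferroni_threshold: float | None = None,
) -> DistortionResult:
    """Chi-square test of one NR-BC chromosome against the 1:1 ratio.

    In the non-recombinant backcross each chromosome is wholly HET or
    wholly HOM_P2, expected in equal numbers; df = 1.
    """
    n = n_het + n_hom_p2
    if n == 0:
        raise ValueError("no scored individuals for this chromosome")
    observed = np.array([n_het, n_hom_p2], dtype=float)
    expected = np.array([n / 2.0, n / 2.0])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(_chi2.sf(chi2, df=1))
    return DistortionResult(
        marker=chromosome,
        cohort=Cohort.NRBC_ADULT_MALE.value,
        counts=GenotypeCounts(n_het=n_het, n_hom_p1=0, n_hom_p2=n_hom_p2),
        expected=tuple(expected),
        chi2=chi2,
        df=1,
        p=p,
        tier=_tier(p, bonferroni_threshold),
        direction=_directions(observed, expected, ["het", "hom_p2"]),
    )


def nrbc_chromosome_states(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Summarize each NR-BC individual to one state per chromosome.

    Returns (chromosome labels, states) with states coded 1 = HET,
    2 = HOM_P2 and 0 = unscorable (all calls missing, or a tie).  The
    state is the majority call over the chromosome's markers; HOM_P1
    artifacts vote with HET, since an AA miscall can only arise from a
    true heterozygote in this design.
    """
    mask = gm.cohort_mask(Cohort.NRBC_ADULT_MALE)
    if not mask.any():
        raise ValueError("no NR-BC individuals in matrix")
    calls = gm.calls[mask]
    chroms: list[str] = []
    for m in gm.markers:
        if m.chromosome is None:
            raise ValueError(f"marker {m.name!r} has no chromosome assignment")
        if m.chromosome not in chroms:
            chroms.append(m.chromosome)
    states = np.zeros((calls.shape[0], len(chroms)), dtype=np.int8)
    for ci, chrom in enumerate(chroms):
        js = [j for j, m in enumerate(gm.markers) if m.chromosome == chrom]
        sub = calls[:, js]
        het_votes = ((sub == Genotype.HET) | (sub == Genotype.HOM_P1)).sum(axis=1)
        hom_votes = (sub == Genotype.HOM_P2).sum(axis=1)
        states[:, ci] = np.where(
            het_votes > hom_votes, 1, np.where(hom_votes > het_votes, 2, 0)
        )
    return chroms, states


def scan_nrbc(gm: GenotypeMatrix) -> DistortionScan:
    """Chromosome-level 1:1 scan of the non-recombinant backcross.

    Each individual contributes one state per chromosome (majority over
    its markers; ties and all-missing chromosomes are excluded).  The
    Bonferroni threshold is 0.05 / (number of chromosomes).
    """
    chroms, states = nrbc_chromosome_states(gm)
    threshold = 0.05 / len(chroms)
    results = [
        nrbc_chromosome_test(
            int((states[:, ci] == 1).sum()),
            int((states[:, ci] == 2).sum()),
            chromosome=chrom,
            bonferroni_threshold=threshold,
        )
        for ci, chrom in enumerate(chroms)
    ]
    return DistortionScan(results, threshold)
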