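"""Two-locus epistasis tests and NR-BC inter-chromosome linkage
disequilibrium.

For each pair of physically unlinked markers, the observed counts of
two-locus genotype combinations are compared with the multiplicative
expectation formed from the two single-locus marginal frequencies
(chi-square goodness of fit).  Two class conventions are supported:

``ordered9``
    all nine ordered genotype combinations, df = 8 (the default: the
    degrees of freedom implied by published chi-square/p pairings for
    this style of scan);
``pooled6``
    the six unordered combinations (mixed classes pool their two
    ordered assignments), df = 5.

Each class carries a signed contribution sign(obs-exp) * (obs-exp)^2 /
exp; the absolute contributions sum exactly to the chi-square.  In the
non-recombinant backcross, association between whole-chromosome states
(HET vs HOM_P2) is tested per chromosome pair with a 2x2 Pearson
independence chi-square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .genotypes import Cohort, GenotypeMatrix
from .distortion import nrbc_chromosome_states
from .linkage import pair_count_table

__all__ = [
    "EpistasisResult",
    "EpistasisScan",
    "LDResult",
    "expected_pair_frequencies",
    "pair_epistasis_test",
    "scan_pairs",
    "nrbc_ld_test",
    "scan_nrbc_ld",
    "class_labels",
    "epistasis_pvalue",
]

CLASS_MODES = ("ordered9", "pooled6")
_GENO_LABEL = {0: "SDSD", 1: "SDSC", 2: "SCSC"}  # P1 = SD, P2 = SC

#: unordered class index pairs for pooled6, in conventional order
_POOLED6 = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def class_labels(class_mode: str) -> list[str]:
    if class_mode == "ordered9":
        return [
            f"{_GENO_LABEL[a]}/{_GENO_LABEL[b]}"
            for a in range(3)
            for b in range(3)
        ]
    if class_mode == "pooled6":
        return [f"{_GENO_LABEL[a]}/{_GENO_LABEL[b]}" for a, b in _POOLED6]
    raise ValueError(f"unknown class_mode {class_mode!r}; choose from {CLASS_MODES}")


def _df(class_mode: str) -> int:
    return {"ordered9": 8, "pooled6": 5}[class_mode]


def epistasis_pvalue(chi2: float, class_mode: str = "ordered9") -> float:
    """Upper-tail p-value of the pair test statistic at its class df."""
    if class_mode not in CLASS_MODES:
        raise ValueError(f"unknown class_mode {class_mode!r}; choose from {CLASS_MODES}")
    return float(_chi2.sf(chi2, df=_df(class_mode)))


def expected_pair_frequencies(
    marginals_a, marginals_b, class_mode: str = "ordered9"
) -> np.ndarray:
    """Multiplicative expected class frequencies from two marginal triples.

    ``ordered9`` returns the 9 products p_a(g) p_b(h) (row-major in g);
    ``pooled6`` returns the six unordered classes, each mixed class
    pooling its two ordered assignments, e.g.
    P(SDSD/SDSC) = p_a(SDSD) p_b(SDSC) + p_a(SDSC) p_b(SDSD).
    """
    pa = np.asarray(marginals_a, dtype=float)
    pb = np.asarray(marginals_b, dtype=float)
    for name, p in (("marginals_a", pa), ("marginals_b", pb)):
        if p.shape != (3,):
            raise ValueError(f"{name} must be a genotype frequency triple")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"{name} must be non-negative and sum to 1")
    outer = np.outer(pa, pb)
    if class_mode == "ordered9":
        return outer.ravel()
    if class_mode == "pooled6":
        return np.array(
            [outer[a, b] if a == b else outer[a, b] + outer[b, a] for a, b in _POOLED6]
        )
    raise ValueError(f"unknown class_mode {class_mode!r}; choose from {CLASS_MODES}")


@dataclass
class EpistasisResult:
    marker_a: str
    marker_b: str
    class_mode: str
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    contributions: np.ndarray  # signed: sign(obs-exp) * (obs-exp)^2 / exp
    n: int
    low_expected: bool  # any expected class count < 5

    @property
    def labels(self) -> list[str]:
        return class_labels(self.class_mode)


def pair_epistasis_test(
    counts,
    class_mode: str = "ordered9",
    marker_a: str = "A",
    marker_b: str = "B",
) -> EpistasisResult:
    """Goodness-of-fit of a 3x3 two-locus table to multiplicative
    expectations built from its own marginals.

    Degrees of freedom equal (number of classes - 1) with no reduction
    for the estimated marginals, matching the goodness-of-fit reading
    of the statistic.  Classes with zero expectation (degenerate
    marginals) are dropped from both sums.  Cells with expected count
    below 5 set ``low_expected`` rather than being pooled.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (3, 3):
        raise ValueError("counts must be a 3x3 two-locus table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty two-locus table")
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    expected = expected_pair_frequencies(pa, pb, class_mode) * n
    if class_mode == "ordered9":
        observed = table.ravel()
    else:
        observed = np.array(
            [table[a, b] if a == b else table[a, b] + table[b, a] for a, b in _POOLED6]
        )
    diff = observed - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, np.sign(diff) * diff**2 / expected, 0.0)
    chi2 = float(np.abs(contrib).sum())
    return EpistasisResult(
        marker_a=marker_a,
        marker_b=marker_b,
        class_mode=class_mode,
        observed=observed,
        expected=expected,
        chi2=chi2,
        df=_df(class_mode),
        p=epistasis_pvalue(chi2, class_mode),
        contributions=contrib,
        n=int(n),
        low_expected=bool((expected[expected > 0] < 5).any()),
    )


@dataclass
class EpistasisScan:
    results: list[EpistasisResult]
    n_groups: int
    bonferroni_denominator: int  # ordered pairs of distinct linkage groups

    @property
    def n_p05(self) -> int:
        return sum(r.p < 0.05 for r in self.results)

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / self.bonferroni_denominator

    def summary(self) -> dict:
        return {
            "n_pairs": len(self.results),
            "n_p05": self.n_p05,
            "n_groups": self.n_groups,
            "bonferroni_denominator": self.bonferroni_denominator,
            "bonferroni_threshold": self.bonferroni_threshold,
            "n_bonferroni": sum(r.p < self.bonferroni_threshold for r in self.results),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "marker_a": r.marker_a,
                "marker_b": r.marker_b,
                "class_mode": r.class_mode,
                "n": r.n,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "low_expected": r.low_expected,
            }
            row.update(
                {f"contrib[{lab}]": c for lab, c in zip(r.labels, r.contributions)}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def scan_pairs(
    gm: GenotypeMatrix,
    cohort: Cohort | str,
    groups: dict[str, str],
    class_mode: str = "ordered9",
) -> EpistasisScan:
    """Epistasis scan over every pair of markers in different groups.

    ``groups`` assigns each marker to a linkage group (or physical
    chromosome); same-group pairs are excluded, since linkage itself
    produces non-multiplicative two-locus frequencies.  The Bonferroni
    denominator is the number of ordered pairs of distinct groups,
    G x (G-1) (132 for 12 groups).
    """
    missing = [m for m in gm.marker_names if m not in groups]
    if missing:
        raise ValueError(f"group assignment missing markers: {missing[:5]}")
    n_groups = len(set(groups[m] for m in gm.marker_names))
    results = []
    for a, b in itertools.combinations(gm.marker_names, 2):
        if groups[a] == groups[b]:
            continue
        table = pair_count_table(gm, a, b, cohort)
        if table.sum() == 0:
            continue
        results.append(pair_epistasis_test(table, class_mode, marker_a=a, marker_b=b))
    return EpistasisScan(
        results,
        n_groups=n_groups,
        bonferroni_denominator=n_groups * (n_groups - 1),
    )


@dataclass
class LDResult:
    """Association between two NR-BC chromosomes' whole-chromosome states."""

    chrom_a: str
    chrom_b: str
    counts: np.ndarray  # 2x2: rows chrom_a state (HET, HOM_P2), cols chrom_b
    chi2: float
    df: int
    p: float
    testable: bool  # False when a marginal row/column is empty


def nrbc_ld_test(counts, chrom_a: str = "A", chrom_b: str = "B") -> LDResult:
    """Pearson chi-square of independence on a 2x2 chromosome-state table.

    Rows are the first chromosome's state (HET, HOM_P2), columns the
    second's.  A zero marginal makes the pair untestable; the result is
    flagged rather than raised.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty chromosome-state table")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return LDResult(chrom_a, chrom_b, table, 0.0, 1, 1.0, testable=False)
    expected = np.outer(rows, cols) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return LDResult(chrom_a, chrom_b, table, chi2, 1, float(_chi2.sf(chi2, df=1)), True)


def scan_nrbc_ld(gm: GenotypeMatrix) -> list[LDResult]:
    """Pairwise inter-chromosome LD scan of the non-recombinant backcross.

    Each individual contributes one state per chromosome (majority
    call); individuals unscorable on either chromosome drop out of that
    pair only.
    """
    chroms, states = nrbc_chromosome_states(gm)
    results = []
    for (ia, ca), (ib, cb) in itertools.combinations(enumerate(chroms), 2):
        sa, sb = states[:, ia], states[:, ib]
        ok = (sa > 0) & (sb > 0)
        table = np.zeros((2, 2))
        np.add.at(table, (sa[ok] - 1, sb[ok] - 1), 1)
        results.append(nrbc_ld_test(table, ca, cb))
    return results
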