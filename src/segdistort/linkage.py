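"""Two-point linkage analysis, Kosambi distances, and map summaries.

Recombination fractions are estimated per marker pair from 3x3
two-locus genotype count tables of a phase-known F2 intercross
(both F1 parents heterozygous, coupling phase).  Two gametic models
are supported:

``symmetric``
    both parents recombine with the same fraction r (the convention of
    standard mapping software);
``female_achiasmatic``
    only the male parent recombines; female gametes are intact parental
    haplotypes.  Under this model the double-homozygote "corner"
    classes HOM_P1/HOM_P2 and HOM_P2/HOM_P1 are impossible.

When the true process is achiasmatic but the symmetric model is fitted,
the estimate converges to roughly 1 - sqrt(1 - r_male) (about half the
male-map fraction for close linkage), so symmetric-model map lengths
systematically understate the male map.  Both behaviours are exercised
in the test-suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

from .genotypes import Cohort, Genotype, GenotypeMatrix

__all__ = [
    "TwoPointResult",
    "LinkageGroupMap",
    "MapSummary",
    "kosambi_cm",
    "kosambi_r",
    "estimate_two_point",
    "pair_count_table",
    "all_pair_tables",
    "group_markers",
    "order_group",
    "build_map",
    "map_summary",
    "genome_coverage",
]

SEX_MODELS = ("symmetric", "female_achiasmatic")


# ---------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance d = 25 ln[(1+2r)/(1-2r)] in centimorgans.

    Accepts scalars or arrays of recombination fractions in [0, 0.5).
    """
    r = np.asarray(r, dtype=float)
    if ((r < 0) | (r >= 0.5)).any():
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d):
    """Inverse Kosambi: r = tanh(d/50)/2 for map distance d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------

@dataclass
class TwoPointResult:
    """Maximum-likelihood two-point linkage estimate for one pair."""

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    p_linkage: float
    n_informative: int


def _cell_probs(r, model: str) -> np.ndarray:
    """Genotype-class probabilities P[g_a, g_b] (3x3) given r.

    Vectorized: r may be an array, giving output shape r.shape + (3, 3).
    """
    r = np.asarray(r, dtype=float)
    p = (1 - r) / 2  # parental gamete probability (per class)
    q = r / 2        # recombinant gamete probability (per class)
    out = np.empty(r.shape + (3, 3))
    if model == "symmetric":
        out[..., 0, 0] = out[..., 2, 2] = p * p
        out[..., 0, 2] = out[..., 2, 0] = q * q
        out[..., 0, 1] = out[..., 1, 0] = out[..., 1, 2] = out[..., 2, 1] = 2 * p * q
        out[..., 1, 1] = 2 * (p * p + q * q)
    elif model == "female_achiasmatic":
        out[..., 0, 0] = out[..., 2, 2] = (1 - r) / 4
        out[..., 0, 2] = out[..., 2, 0] = 0.0
        out[..., 0, 1] = out[..., 1, 0] = out[..., 1, 2] = out[..., 2, 1] = r / 4
        out[..., 1, 1] = (1 - r) / 2
    else:
        raise ValueError(f"unknown sex_model {model!r}; choose from {SEX_MODELS}")
    return out


def _loglik(tables: np.ndarray, r: np.ndarray, model: str) -> np.ndarray:
    """Multinomial log-likelihood of each table at its r (natural log).

    Cells with zero model probability and zero count contribute 0; a
    positive count in a zero-probability cell yields -inf.
    """
    probs = _cell_probs(r, model)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    terms = tables * np.where(tables > 0, logp, 0.0)
    return terms.reshape(tables.shape[0], -1).sum(axis=1)


def _em_symmetric(tables: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """EM for r under the symmetric model, vectorized over K tables.

    E-step: the double-heterozygote class splits between both-parental
    and both-recombinant gamete origins with weights
    (1-r)^2 / ((1-r)^2 + r^2) and r^2 / ((1-r)^2 + r^2); every other
    class has a determined recombinant-gamete count.
    M-step: r = E[recombinant gametes] / (2n).
    """
    t = tables.astype(float)
    n = t.reshape(len(t), -1).sum(axis=1)
    # determined recombinant gametes: single-het edges carry 1, corners 2
    fixed = (
        t[:, 0, 1] + t[:, 1, 0] + t[:, 1, 2] + t[:, 2, 1]
        + 2 * (t[:, 0, 2] + t[:, 2, 0])
    )
    n11 = t[:, 1, 1]
    r = np.full(len(t), 0.25)
    for _ in range(max_iter):
        w = r**2 / ((1 - r) ** 2 + r**2)
        r_new = np.clip((fixed + 2 * w * n11) / (2 * n), 0.0, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    return r


def _mle_achiasmatic(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form MLE under the achiasmatic model.

    Recombinant male gametes are exactly the single-heterozygote
    classes; the double-heterozygote class is unambiguously
    non-recombinant.  The corner classes are impossible under the
    model (they require a recombinant female gamete) and are excluded
    from the fit as genotyping artifacts.  Returns (r_hat, tables with
    corners zeroed).
    """
    t = tables.astype(float)
    t = t.copy()
    t[:, 0, 2] = 0.0
    t[:, 2, 0] = 0.0
    n = t.reshape(len(t), -1).sum(axis=1)
    rec = t[:, 0, 1] + t[:, 1, 0] + t[:, 1, 2] + t[:, 2, 1]
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, np.clip(rec / np.maximum(n, 1), 0.0, 0.5), np.nan)
    return r, t


def estimate_two_point_many(
    tables: np.ndarray, sex_model: str = "symmetric"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-point estimation over K tables of shape (K, 3, 3).

    Returns arrays (r_hat, lod, p_linkage, n_informative).
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim != 3 or tables.shape[1:] != (3, 3):
        raise ValueError("tables must have shape (K, 3, 3)")
    if (tables < 0).any():
        raise ValueError("counts must be non-negative")
    if sex_model == "symmetric":
        fit_tables = tables
        r = _em_symmetric(tables)
    elif sex_model == "female_achiasmatic":
        r, fit_tables = _mle_achiasmatic(tables)
    else:
        raise ValueError(f"unknown sex_model {sex_model!r}; choose from {SEX_MODELS}")
    n = tables.reshape(len(tables), -1).sum(axis=1)
    ll_hat = _loglik(fit_tables, r, sex_model)
    ll_null = _loglik(fit_tables, np.full_like(r, 0.5), sex_model)
    g = np.maximum(2.0 * (ll_hat - ll_null), 0.0)
    lod = g / (2.0 * np.log(10.0))
    p = _chi2.sf(g, df=1)
    p = np.where(g <= 0, 1.0, p)
    return r, lod, p, n.astype(int)


def estimate_two_point(
    counts,
    sex_model: str = "symmetric",
    marker_a: str = "A",
    marker_b: str = "B",
) -> TwoPointResult:
    """ML recombination fraction for one 3x3 two-locus count table.

    Rows index the genotype at the first marker, columns at the second
    (order HOM_P1, HET, HOM_P2).  The likelihood-ratio test against
    r = 0.5 gives the LOD score and the linkage p-value from the
    chi-square(1) upper tail of 2 ln LR (slightly conservative at the
    boundary, where the exact null is a half-half mixture).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 table")
    if counts.sum() <= 0:
        raise ValueError("empty count table")
    r, lod, p, n = estimate_two_point_many(counts[None], sex_model)
    return TwoPointResult(
        marker_a, marker_b, float(r[0]), float(lod[0]), float(p[0]), int(n[0])
    )


def pair_count_table(
    gm: GenotypeMatrix, marker_a: str, marker_b: str, cohort: Cohort | str
) -> np.ndarray:
    """3x3 pairwise-complete genotype count table for one marker pair."""
    ja, jb = gm.marker_index(marker_a), gm.marker_index(marker_b)
    mask = gm.cohort_mask(cohort)
    a = gm.calls[mask, ja]
    b = gm.calls[mask, jb]
    ok = (a != Genotype.MISSING) & (b != Genotype.MISSING)
    table = np.zeros((3, 3))
    np.add.at(table, (a[ok], b[ok]), 1)
    return table


def all_pair_tables(
    gm: GenotypeMatrix, cohort: Cohort | str
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Count tables for every unordered marker pair (pairwise-complete).

    Returns (pairs, tables) with tables of shape (n_pairs, 3, 3).
    Individuals missing either call drop out of that pair only.
    """
    mask = gm.cohort_mask(cohort)
    calls = gm.calls[mask]
    names = gm.marker_names
    # one-hot over genotype classes, zero where missing
    onehot = np.zeros(calls.shape + (3,))
    for g in range(3):
        onehot[..., g] = calls == g
    # joint[a, b, g, h] = number of individuals with genotype g at a, h at b
    joint = np.einsum("iag,ibh->abgh", onehot, onehot)
    iu, ju = np.triu_indices(len(names), k=1)
    pairs = [(names[i], names[j]) for i, j in zip(iu, ju)]
    return pairs, joint[iu, ju]


# ---------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------

def group_markers(
    markers: list[str],
    results: list[TwoPointResult],
    alpha: float = 0.001,
) -> list[list[str]]:
    """Partition markers by single-linkage closure of {p_linkage < alpha}.

    Markers with no significant partner become singleton groups.  The
    returned groups preserve marker input order (group ordered by first
    member's appearance).
    """
    index = {m: i for i, m in enumerate(markers)}
    parent = list(range(len(markers)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for res in results:
        if res.p_linkage < alpha:
            ra, rb = find(index[res.marker_a]), find(index[res.marker_b])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[int, list[str]] = {}
    for m in markers:
        groups.setdefault(find(index[m]), []).append(m)
    return [groups[root] for root in sorted(groups)]


def _sarf(order: list[int], dist: np.ndarray) -> float:
    return sum(dist[a, b] for a, b in zip(order, order[1:]))


def order_group(
    markers: list[str],
    r_lookup: dict[tuple[str, str], float],
    exhaustive_limit: int = 8,
) -> list[str]:
    """Order a linkage group by minimum sum of adjacent recombination
    fractions (SARF).

    Exhaustive search up to ``exhaustive_limit`` markers; greedy
    nearest-neighbour insertion with 2-opt refinement beyond.  The
    orientation is canonicalized so the first marker name sorts before
    the last.  Pairs absent from ``r_lookup`` count as unlinked (0.5).
    """
    m = len(markers)
    if m < 2:
        raise ValueError("ordering requires at least 2 markers")
    dist = np.full((m, m), 0.5)
    np.fill_diagonal(dist, 0.0)
    for i, a in enumerate(markers):
        for j, b in enumerate(markers):
            if i < j:
                r = r_lookup.get((a, b), r_lookup.get((b, a), 0.5))
                dist[i, j] = dist[j, i] = r

    if m <= exhaustive_limit:
        best = min(
            (list(perm) for perm in itertools.permutations(range(m))),
            key=lambda o: (_sarf(o, dist), o),
        )
    else:
        # greedy nearest-neighbour from every start, then 2-opt
        candidates = []
        for start in range(m):
            left = set(range(m)) - {start}
            order = [start]
            while left:
                nxt = min(left, key=lambda j: (dist[order[-1], j], j))
                order.append(nxt)
                left.remove(nxt)
            candidates.append(order)
        best = min(candidates, key=lambda o: _sarf(o, dist))
        improved = True
        while improved:
            improved = False
            for i in range(m - 1):
                for j in range(i + 1, m):
                    cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                    if _sarf(cand, dist) < _sarf(best, dist) - 1e-15:
                        best = cand
                        improved = True
    ordered = [markers[i] for i in best]
    if ordered[0] > ordered[-1]:
        ordered.reverse()
    return ordered


# ---------------------------------------------------------------------
# maps and summaries
# ---------------------------------------------------------------------

@dataclass
class LinkageGroupMap:
    """An ordered linkage group with cumulative Kosambi positions."""

    group_id: str
    markers: list[str]
    positions_cM: list[float]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.positions_cM):
            raise ValueError("markers and positions must align")
        if any(b < a for a, b in zip(self.positions_cM, self.positions_cM[1:])):
            raise ValueError("positions must be non-decreasing")

    @property
    def m(self) -> int:
        return len(self.markers)

    @property
    def group_length(self) -> float:
        return self.positions_cM[-1] - self.positions_cM[0] if self.m > 1 else 0.0


@dataclass
class MapSummary:
    """Whole-map statistics: lengths, spacing, and genome coverage."""

    total_length: float    # sum of group lengths (multi-marker groups)
    d: float               # mean intermarker distance, cM
    n: int                 # markers assigned to multi-marker groups
    corrected_length: float  # L, after the (+2 cM) x (m+1)/(m-1) correction
    coverage: float        # c = 1 - exp(-2 d n / L)
    n_groups: int
    n_singletons: int


def build_map(
    gm: GenotypeMatrix,
    cohort: Cohort | str,
    sex_model: str = "symmetric",
    alpha: float = 0.001,
) -> tuple[list[LinkageGroupMap], list[TwoPointResult]]:
    """Two-point map construction for one cohort.

    Pipeline: pairwise ML estimates -> single-linkage grouping at the
    ``alpha`` linkage criterion -> SARF ordering -> adjacent Kosambi
    distances accumulated from 0.  Deterministic (no RNG anywhere).
    Returns (maps, all pairwise results).
    """
    if len(gm.markers) < 2:
        raise ValueError("mapping requires at least 2 markers")
    if not gm.cohort_mask(cohort).any():
        raise ValueError(f"cohort {Cohort(cohort).value!r} is empty")
    pairs, tables = all_pair_tables(gm, cohort)
    ok = tables.reshape(len(tables), -1).sum(axis=1) > 0
    r, lod, p, n = estimate_two_point_many(tables[ok], sex_model)
    results = [
        TwoPointResult(a, b, float(ri), float(li), float(pi), int(ni))
        for (a, b), ri, li, pi, ni in zip(
            [pr for pr, keep in zip(pairs, ok) if keep], r, lod, p, n
        )
    ]
    r_lookup = {(res.marker_a, res.marker_b): res.r_hat for res in results}
    groups = group_markers(gm.marker_names, results, alpha=alpha)

    maps = []
    for gi, members in enumerate(groups):
        group_id = f"LG{gi + 1:02d}"
        if len(members) == 1:
            maps.append(LinkageGroupMap(group_id, members, [0.0]))
            continue
        ordered = order_group(members, r_lookup)
        adj = np.array(
            [
                r_lookup.get((a, b), r_lookup.get((b, a), 0.5))
                for a, b in zip(ordered, ordered[1:])
            ]
        )
        # numerical guard: an adjacent estimate pinned at 0.5 would map to
        # infinite distance; clip just inside the Kosambi domain
        adj = np.minimum(adj, 0.5 - 1e-9)
        positions = np.concatenate([[0.0], np.cumsum(kosambi_cm(adj))])
        maps.append(LinkageGroupMap(group_id, ordered, positions.tolist()))
    return maps, results


def genome_coverage(d: float, n: int, length: float) -> float:
    """Expected genome coverage c = 1 - exp(-2 d n / L).

    ``d`` is the mean intermarker distance (cM), ``n`` the number of
    markers assigned to linkage groups, ``length`` the corrected map
    length L (cM).  Strictly increasing in d and n, decreasing in L.
    """
    if length <= 0:
        raise ValueError("corrected length must be > 0")
    return 1.0 - float(np.exp(-2.0 * d * n / length))


def map_summary(maps: list[LinkageGroupMap]) -> MapSummary:
    """Total, corrected length and coverage over a set of linkage groups.

    Singleton groups are excluded from every statistic: the per-group
    length correction (group_length + 2) x (m+1)/(m-1) is undefined at
    m = 1, and mean spacing d = total_length / (number of adjacent
    intervals) only involves multi-marker groups.
    """
    multi = [g for g in maps if g.m >= 2]
    if not multi:
        raise ValueError("map correction undefined: every group is a singleton")
    total = sum(g.group_length for g in multi)
    intervals = sum(g.m - 1 for g in multi)
    n = sum(g.m for g in multi)
    d = total / intervals
    corrected = sum((g.group_length + 2.0) * (g.m + 1) / (g.m - 1) for g in multi)
    return MapSummary(
        total_length=total,
        d=d,
        n=n,
        corrected_length=corrected,
        coverage=genome_coverage(d, n, corrected),
        n_groups=len(maps),
        n_singletons=len(maps) - len(multi),
    )
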