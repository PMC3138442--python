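"""Gene-drop simulator for an SD x SC copepod mapping cross.

Emulates the study design this package analyses: an F2 intercross
between two inbred lines of a harpacticoid copepod whose females are
achiasmatic (no crossing-over in female meiosis), sampled once at
hatching (nauplii) and once at adulthood (males only), plus a
non-recombinant backcross (F1 female x P2 male) in which every offspring
chromosome is either fully heterozygous or fully P2-homozygous.

Viability selection acts between life stages through relative genotype
viabilities in [0, 1]; genotyping artifacts (heterozygote undercalling,
missing calls) are injected last.  All randomness flows from a single
``numpy.random.Generator``, so a seed fixes every output byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .genotypes import (
    Cohort,
    Genotype,
    GenotypeMatrix,
    Individual,
    MarkerClass,
    MarkerDef,
    Sex,
)
from .linkage import kosambi_r

__all__ = [
    "GenomeLayout",
    "SelectionRegime",
    "ErrorModel",
    "CrossConfig",
    "default_layout",
    "preset_regime",
    "PRESET_NAMES",
    "meiosis_female",
    "meiosis_male",
    "simulate_f2_cohorts",
    "simulate_nrbc",
    "apply_genotyping_artifacts",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosomes as ordered (marker, male-map position in cM) lists."""

    chromosomes: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, markers in self.chromosomes:
            pos = [p for _, p in markers]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"chromosome {label}: positions must be strictly increasing"
                )
            for name, _ in markers:
                if name in seen:
                    raise ValueError(f"duplicate marker name {name!r}")
                seen.add(name)

    @property
    def marker_names(self) -> list[str]:
        return [name for _, markers in self.chromosomes for name, _ in markers]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def chromosome_of(self) -> dict[str, str]:
        return {
            name: label
            for label, markers in self.chromosomes
            for name, _ in markers
        }

    def marker_defs(
        self, microsatellites: frozenset[str] = frozenset()
    ) -> list[MarkerDef]:
        return [
            MarkerDef(
                name,
                chromosome=label,
                position_cM=pos,
                marker_class=(
                    MarkerClass.MICROSATELLITE
                    if name in microsatellites
                    else MarkerClass.SNP
                ),
            )
            for label, markers in self.chromosomes
            for name, pos in markers
        ]


#: microsatellite names used by the default panel (anchor markers)
DEFAULT_MICROSATELLITES = frozenset(
    {"MS030", "MS197", "MS228", "MS480", "MS558", "MS1203", "MS1555", "MS56J2"}
)

# Chromosome labels of the default layout; presets key off "2", "7", "10".
_DEFAULT_PLAN = [
    ("1", 5), ("2", 5), ("4", 4), ("5", 4), ("7", 5), ("8", 5),
    ("9", 4), ("10", 5), ("A", 6), ("B", 4), ("C", 5), ("D", 1),
]


def default_layout(spacing_cM: float = 6.5) -> GenomeLayout:
    """The 53-marker, 12-chromosome default panel.

    Eleven multi-marker chromosomes plus one singleton, 52 assigned
    markers over 41 adjacent intervals at a uniform male-map spacing
    (default 6.5 cM), mirroring the marker density of the study panel
    (45 SNPs + 8 anchoring microsatellites).  The eight microsatellites
    sit first on the eight numerically named chromosomes.
    """
    ms_names = ["MS030", "MS197", "MS228", "MS480", "MS558", "MS1203", "MS1555", "MS56J2"]
    snp_iter = iter(f"TC{k:03d}" for k in range(1, 100))
    chroms = []
    ms_i = 0
    for label, m in _DEFAULT_PLAN:
        names = []
        for k in range(m):
            if k == 0 and label.isdigit() and ms_i < len(ms_names):
                names.append(ms_names[ms_i])
                ms_i += 1
            else:
                names.append(next(snp_iter))
        chroms.append(
            (label, tuple((n, k * spacing_cM) for k, n in enumerate(names)))
        )
    return GenomeLayout(tuple(chroms))


@dataclass(frozen=True)
class SelectionRegime:
    """Relative viabilities applied at one life-stage transition.

    ``single_locus`` maps a marker to ``(w_hom_p1, w_het, w_hom_p2)``;
    ``epistatic_pairs`` maps an ordered marker pair to a 3x3 viability
    table indexed ``[genotype_a, genotype_b]``.  Survival probability of
    an individual is the product of all applicable viabilities,
    normalized by the regime's maximum product so the fittest genotype
    survives with probability 1.
    """

    stage: str = "hatching_to_adult"  # or "pre_hatching"
    single_locus: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    epistatic_pairs: dict[tuple[str, str], tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("pre_hatching", "hatching_to_adult"):
            raise ValueError(f"unknown selection stage {self.stage!r}")
        for marker, ws in self.single_locus.items():
            w = np.asarray(ws, dtype=float)
            if w.shape != (3,) or (w < 0).any() or (w > 1).any():
                raise ValueError(f"viabilities for {marker!r} must be 3 values in [0, 1]")
            if not (w > 0).any():
                raise ValueError(f"marker {marker!r}: all genotypes inviable")
        for pair, table in self.epistatic_pairs.items():
            t = np.asarray(table, dtype=float)
            if t.shape != (3, 3) or (t < 0).any() or (t > 1).any():
                raise ValueError(f"pair {pair}: viability table must be 3x3 in [0, 1]")
            if not (t > 0).any():
                raise ValueError(f"pair {pair}: all genotype combinations inviable")

    @property
    def is_null(self) -> bool:
        return not self.single_locus and not self.epistatic_pairs


@dataclass(frozen=True)
class ErrorModel:
    """Genotyping artifacts: undercalled heterozygotes and missing calls.

    A true heterozygote is reported as a random homozygote with
    probability ``het_undercall_rate``; independently, any call is lost
    to MISSING with probability ``missing_rate`` (undercall first).
    """

    het_undercall_rate: float = 0.0
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("het_undercall_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CrossConfig:
    """Full description of one simulated cross: genome, selection,
    cohort sizes, error model and seed.

    Defaults reproduce the study's genotyped samples: 190 F2 nauplii
    from 4 F1 pairs, 205 F2 adult males from 25 F1 pairs, and 39
    non-recombinant-backcross adult males from 7 pairs.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    regimes: tuple[SelectionRegime, ...] = ()
    n_nauplii: int = 190
    n_adult_males: int = 205
    n_nrbc_males: int = 39
    n_f1_pairs_nauplii: int = 4
    n_f1_pairs_adult: int = 25
    n_f1_pairs_nrbc: int = 7
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_nauplii", "n_adult_males", "n_nrbc_males",
            "n_f1_pairs_nauplii", "n_f1_pairs_adult", "n_f1_pairs_nrbc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        known = set(self.layout.marker_names)
        for regime in self.regimes:
            for marker in regime.single_locus:
                if marker not in known:
                    raise ValueError(f"selection regime references unknown marker {marker!r}")
            for a, b in regime.epistatic_pairs:
                for marker in (a, b):
                    if marker not in known:
                        raise ValueError(f"selection regime references unknown marker {marker!r}")

    def digest(self) -> str:
        """Stable hash of the configuration (for run metadata)."""
        blob = json.dumps(_config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


PRESET_NAMES = ("null", "chr10_sd_deficit", "het_excess_2_7")


def preset_regime(name: str, layout: GenomeLayout | None = None) -> SelectionRegime:
    """Named viability regimes encoding the study's qualitative patterns.

    - ``null``: no selection.
    - ``chr10_sd_deficit``: near-lethality of the P1 (SD) homozygote at
      every chromosome-10 marker (w_hom_p1 = 0.05), acting between
      hatching and adulthood.
    - ``het_excess_2_7``: P2 (SC) homozygote disadvantage on
      chromosomes 2 and 7 (w_hom_p2 = 0.5, w_het = 1), yielding
      heterozygote excess among adults.
    """
    layout = layout or default_layout()
    chrom_of = layout.chromosome_of()
    if name == "null":
        return SelectionRegime()
    if name == "chr10_sd_deficit":
        loci = {m: (0.05, 1.0, 1.0) for m, c in chrom_of.items() if c == "10"}
    elif name == "het_excess_2_7":
        loci = {m: (1.0, 1.0, 0.5) for m, c in chrom_of.items() if c in ("2", "7")}
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if not loci:
        raise ValueError(f"preset {name!r}: layout has no markers on the target chromosomes")
    return SelectionRegime(stage="hatching_to_adult", single_locus=loci)


# ---------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------

def meiosis_female(hap_a: np.ndarray, hap_b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Achiasmatic female meiosis: one parental haplotype passed intact.

    Either ``hap_a`` or ``hap_b`` is returned whole, each with
    probability 1/2; no crossover ever occurs.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    return (hap_a if rng.random() < 0.5 else hap_b).copy()


def meiosis_male(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    recomb: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Male meiosis as a no-interference Markov walk along the chromosome.

    ``recomb[j]`` is the recombination probability of the interval
    between markers j and j+1 (each in [0, 0.5]; the 0.5 endpoint makes
    the flanking markers independent); the walk starts on a random
    homolog and switches independently per interval.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    recomb = np.asarray(recomb, dtype=float)
    if hap_a.shape != hap_b.shape:
        raise ValueError("haplotypes must have equal length")
    if recomb.shape != (len(hap_a) - 1,):
        raise ValueError("need one recombination probability per marker interval")
    if ((recomb < 0) | (recomb > 0.5)).any():
        raise ValueError("interval recombination probabilities must lie in [0, 0.5]")
    state = np.empty(len(hap_a), dtype=np.int8)
    state[0] = rng.integers(0, 2)
    if len(recomb):
        switches = rng.random(len(recomb)) < recomb
        state[1:] = state[0] ^ np.cumsum(switches).astype(np.int8) % 2
    return np.where(state == 0, hap_a, hap_b)


# ---------------------------------------------------------------------
# vectorized gene drop
# ---------------------------------------------------------------------

def _interval_recomb(layout: GenomeLayout) -> list[np.ndarray]:
    """Per-chromosome interval recombination fractions via inverse Kosambi."""
    out = []
    for _, markers in layout.chromosomes:
        pos = np.array([p for _, p in markers], dtype=float)
        out.append(kosambi_r(np.diff(pos)))
    return out


def _draw_f2_batch(layout: GenomeLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n F2 genotype vectors (codes 0/1/2) under female achiasmy."""
    cols = []
    for (_, markers), recomb in zip(layout.chromosomes, _interval_recomb(layout)):
        m = len(markers)
        # maternal gamete: intact F1 haplotype, allele 0 (P1) or 1 (P2)
        maternal = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        # paternal gamete: Markov walk with interval switches
        start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        if m > 1:
            switches = (rng.random((n, m - 1)) < recomb).astype(np.int8)
            states = np.concatenate(
                [start, (start + np.cumsum(switches, axis=1)) % 2], axis=1
            )
        else:
            states = start
        cols.append(maternal + states)  # 0=HOM_P1, 1=HET, 2=HOM_P2
    return np.concatenate(cols, axis=1).astype(np.int8)


def _draw_nrbc_batch(layout: GenomeLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n NR-BC genotype vectors: per chromosome uniformly HET or HOM_P2."""
    cols = []
    for _, markers in layout.chromosomes:
        m = len(markers)
        maternal = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        cols.append(np.repeat(maternal + 1, m, axis=1))  # paternal allele is P2
    return np.concatenate(cols, axis=1).astype(np.int8)


def _survival_probability(
    geno: np.ndarray, layout: GenomeLayout, regimes: list[SelectionRegime]
) -> np.ndarray:
    """Normalized survival probability per individual under the regimes."""
    idx = {name: j for j, name in enumerate(layout.marker_names)}
    w = np.ones(len(geno))
    w_max = 1.0
    for regime in regimes:
        for marker, ws in regime.single_locus.items():
            ws = np.asarray(ws, dtype=float)
            w *= ws[geno[:, idx[marker]]]
            w_max *= ws.max()
        for (a, b), table in regime.epistatic_pairs.items():
            t = np.asarray(table, dtype=float)
            w *= t[geno[:, idx[a]], geno[:, idx[b]]]
            w_max *= t.max()
    return w / w_max


def _select(
    geno: np.ndarray,
    layout: GenomeLayout,
    regimes: list[SelectionRegime],
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean survivor mask (Bernoulli per individual)."""
    if not regimes or all(r.is_null for r in regimes):
        return np.ones(len(geno), dtype=bool)
    p = _survival_probability(geno, layout, regimes)
    return rng.random(len(geno)) < p


def _stage_regimes(config: CrossConfig, stage: str) -> list[SelectionRegime]:
    return [r for r in config.regimes if r.stage == stage]


def _collect_cohort(
    config: CrossConfig,
    draw,
    n_wanted: int,
    stages: list[str],
    males_only: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample genotypes until n_wanted survivors are collected.

    Returns (genotypes, sexes) where sexes are Sex codes (0 male,
    1 female), drawn Bernoulli(0.5) independent of genotype.
    """
    got_geno: list[np.ndarray] = []
    got_sex: list[np.ndarray] = []
    n_have = 0
    batch = max(2 * n_wanted, 64)
    while n_have < n_wanted:
        geno = draw(config.layout, batch, rng)
        keep = np.ones(len(geno), dtype=bool)
        for stage in stages:
            keep &= _select(geno, config.layout, _stage_regimes(config, stage), rng)
        sex = rng.integers(0, 2, size=len(geno), dtype=np.int8)  # 0 male, 1 female
        if males_only:
            keep &= sex == 0
        got_geno.append(geno[keep])
        got_sex.append(sex[keep])
        n_have += int(keep.sum())
    geno = np.concatenate(got_geno)[:n_wanted]
    sex = np.concatenate(got_sex)[:n_wanted]
    return geno, sex


def _make_individuals(
    prefix: str, cohort: Cohort, n: int, n_families: int, sexes: np.ndarray | None
) -> list[Individual]:
    out = []
    for i in range(n):
        sex = Sex.UNKNOWN if sexes is None else (Sex.MALE if sexes[i] == 0 else Sex.FEMALE)
        out.append(
            Individual(
                id=f"{prefix}{i + 1:04d}",
                cohort=cohort,
                family=f"{prefix}F{(i % n_families) + 1:02d}",
                sex=sex,
            )
        )
    return out


def simulate_f2_cohorts(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate the paired F2 cohorts: (nauplii, adult males).

    Every F1 is heterozygous at every marker, so each F2 receives one
    achiasmatic maternal gamete (an intact parental haplotype per
    chromosome) and one recombinant paternal gamete.  Pre-hatching
    selection is applied before the nauplii snapshot; adults additionally
    pass hatching-to-adult selection and are filtered to males.  The
    error model is applied last.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    markers = config.layout.marker_defs(DEFAULT_MICROSATELLITES)

    geno_n, _ = _collect_cohort(
        config, _draw_f2_batch, config.n_nauplii, ["pre_hatching"], False, rng
    )
    nauplii = GenotypeMatrix(
        _make_individuals("NPL", Cohort.F2_NAUPLII, config.n_nauplii,
                          config.n_f1_pairs_nauplii, None),
        markers,
        geno_n,
    )

    geno_a, sex_a = _collect_cohort(
        config, _draw_f2_batch, config.n_adult_males,
        ["pre_hatching", "hatching_to_adult"], True, rng,
    )
    adults = GenotypeMatrix(
        _make_individuals("ADM", Cohort.F2_ADULT_MALE, config.n_adult_males,
                          config.n_f1_pairs_adult, sex_a),
        markers,
        geno_a,
    )

    nauplii = apply_genotyping_artifacts(nauplii, config.error_model, rng=rng)
    adults = apply_genotyping_artifacts(adults, config.error_model, rng=rng)
    return nauplii, adults


def simulate_nrbc(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Simulate the non-recombinant backcross (F1 female x P2 male).

    Each chromosome is inherited intact from the achiasmatic F1 mother
    (whole-P1 or whole-P2, independently per chromosome) alongside a
    whole-P2 paternal chromosome, so every chromosome is uniformly HET
    or HOM_P2 within an individual.  Selection and the error model are
    applied as for the F2 adults.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    markers = config.layout.marker_defs(DEFAULT_MICROSATELLITES)
    geno, sex = _collect_cohort(
        config, _draw_nrbc_batch, config.n_nrbc_males,
        ["pre_hatching", "hatching_to_adult"], True, rng,
    )
    assert not (geno == Genotype.HOM_P1).any(), "NR-BC truth violates achiasmy"
    gm = GenotypeMatrix(
        _make_individuals("NRB", Cohort.NRBC_ADULT_MALE, config.n_nrbc_males,
                          config.n_f1_pairs_nrbc, sex),
        markers,
        geno,
    )
    return apply_genotyping_artifacts(gm, config.error_model, rng=rng)


def apply_genotyping_artifacts(
    gm: GenotypeMatrix,
    em: ErrorModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Inject genotyping errors: het undercall, then missingness.

    Each HET is independently rewritten to HOM_P1 or HOM_P2 (equal
    odds) with probability ``em.het_undercall_rate``; each call is then
    independently set to MISSING with probability ``em.missing_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    calls = gm.calls.copy()
    if em.het_undercall_rate > 0:
        het = calls == Genotype.HET
        flip = het & (rng.random(calls.shape) < em.het_undercall_rate)
        homs = rng.integers(0, 2, size=calls.shape, dtype=np.int8) * 2  # 0 or 2
        calls[flip] = homs[flip]
    if em.missing_rate > 0:
        lost = rng.random(calls.shape) < em.missing_rate
        calls[lost] = Genotype.MISSING
    import warnings

    with warnings.catch_warnings():
        # artifacts may legitimately create HOM_P1 in NR-BC cohorts
        warnings.simplefilter("ignore")
        return GenotypeMatrix(list(gm.individuals), list(gm.markers), calls)


# ---------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------

def _config_to_dict(config: CrossConfig) -> dict:
    return {
        "seed": config.seed,
        "n_nauplii": config.n_nauplii,
        "n_adult_males": config.n_adult_males,
        "n_nrbc_males": config.n_nrbc_males,
        "n_f1_pairs_nauplii": config.n_f1_pairs_nauplii,
        "n_f1_pairs_adult": config.n_f1_pairs_adult,
        "n_f1_pairs_nrbc": config.n_f1_pairs_nrbc,
        "error_model": {
            "het_undercall_rate": config.error_model.het_undercall_rate,
            "missing_rate": config.error_model.missing_rate,
        },
        "layout": {
            label: [[name, pos] for name, pos in markers]
            for label, markers in config.layout.chromosomes
        },
        "regimes": [
            {
                "stage": r.stage,
                "single_locus": {m: list(w) for m, w in r.single_locus.items()},
                "epistatic_pairs": {
                    f"{a}|{b}": np.asarray(t).tolist()
                    for (a, b), t in r.epistatic_pairs.items()
                },
            }
            for r in config.regimes
        ],
    }


def config_to_yaml(config: CrossConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def config_from_yaml(path) -> CrossConfig:
    """Load a :class:`CrossConfig` from YAML.

    ``layout`` may be the string ``default`` or a mapping of chromosome
    label to ``[[marker, position_cM], ...]``; each regime entry is
    either ``{preset: name}`` or an explicit stage/viability mapping.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    layout_raw = raw.get("layout", "default")
    if isinstance(layout_raw, str):
        if layout_raw != "default":
            raise ValueError(f"unknown layout {layout_raw!r}")
        layout = default_layout()
    else:
        layout = GenomeLayout(
            tuple(
                (str(label), tuple((str(n), float(p)) for n, p in markers))
                for label, markers in layout_raw.items()
            )
        )
    regimes = []
    for entry in raw.get("regimes", []) or []:
        if "preset" in entry:
            regimes.append(preset_regime(entry["preset"], layout))
        else:
            pairs = {
                tuple(key.split("|")): tuple(map(tuple, table))
                for key, table in (entry.get("epistatic_pairs") or {}).items()
            }
            regimes.append(
                SelectionRegime(
                    stage=entry.get("stage", "hatching_to_adult"),
                    single_locus={
                        m: tuple(w) for m, w in (entry.get("single_locus") or {}).items()
                    },
                    epistatic_pairs=pairs,
                )
            )
    em_raw = raw.get("error_model", {}) or {}
    kwargs = {
        k: raw[k]
        for k in (
            "n_nauplii", "n_adult_males", "n_nrbc_males",
            "n_f1_pairs_nauplii", "n_f1_pairs_adult", "n_f1_pairs_nrbc", "seed",
        )
        if k in raw
    }
    return CrossConfig(
        layout=layout,
        regimes=tuple(regimes),
        error_model=ErrorModel(
            het_undercall_rate=float(em_raw.get("het_undercall_rate", 0.0)),
            missing_rate=float(em_raw.get("missing_rate", 0.02)),
        ),
        **kwargs,
    )
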