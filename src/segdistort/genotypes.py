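"""Genotype matrices for biparental mapping crosses.

Codominant calls for an intercross between two inbred parental lines,
P1 (the maternal, SD-type line whose cytoplasm every hybrid carries) and
P2 (the paternal, SC-type line).  Calls are held as small integer codes
in an individuals x markers array; the serialized tokens are ``AA``
(P1/P1 homozygote), ``AB`` (heterozygote), ``BB`` (P2/P2 homozygote)
and ``NA`` (missing).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Cohort",
    "Sex",
    "MarkerClass",
    "MarkerDef",
    "Individual",
    "GenotypeMatrix",
    "GenotypeCounts",
    "GenotypeFormatError",
    "GenotypeParseError",
    "genotype_counts",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "write_marker_map",
]


class Genotype(enum.IntEnum):
    """Diploid call at a codominant marker; codes double as array values."""

    HOM_P1 = 0
    HET = 1
    HOM_P2 = 2
    MISSING = 3


#: serialized tokens, indexed by genotype code
TOKENS = np.array(["AA", "AB", "BB", "NA"])
_TOKEN_TO_CODE = {t: i for i, t in enumerate(TOKENS)}


class Cohort(str, enum.Enum):
    F2_NAUPLII = "f2_nauplii"
    F2_ADULT_MALE = "f2_adult_male"
    NRBC_ADULT_MALE = "nrbc_adult_male"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class MarkerClass(str, enum.Enum):
    SNP = "snp"
    MICROSATELLITE = "microsatellite"


class GenotypeFormatError(ValueError):
    """A table violates the structural contract (missing columns etc.)."""


class GenotypeParseError(ValueError):
    """A cell holds a token outside {AA, AB, BB, NA}."""


@dataclass(frozen=True)
class MarkerDef:
    """A marker: name, optional chromosome assignment and map position."""

    name: str
    chromosome: str | None = None
    position_cM: float | None = None
    marker_class: MarkerClass = MarkerClass.SNP

    def __post_init__(self) -> None:
        if self.position_cM is not None and self.position_cM < 0:
            raise ValueError(f"marker {self.name}: position_cM must be >= 0")


@dataclass(frozen=True)
class Individual:
    id: str
    cohort: Cohort
    family: str
    sex: Sex = Sex.UNKNOWN
    mito: str = "P1"  # every F2 / NR-BC hybrid carries the P1 cytoplasm


@dataclass
class GenotypeCounts:
    """Genotype tallies for one marker within one cohort."""

    n_het: int
    n_hom_p1: int
    n_hom_p2: int
    n_missing: int = 0

    @property
    def n_typed(self) -> int:
        return self.n_het + self.n_hom_p1 + self.n_hom_p2

    @property
    def total(self) -> int:
        return self.n_typed + self.n_missing


@dataclass
class GenotypeMatrix:
    """Rectangular individuals x markers table of codominant calls.

    ``calls[i, j]`` is the :class:`Genotype` code of individual *i* at
    marker *j*.  Cohort, family and sex ride on the individuals, so one
    matrix may mix nauplii, adult males and backcross males.
    """

    individuals: list[Individual]
    markers: list[MarkerDef]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        self.validate()

    # -- structure -----------------------------------------------------

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def cohort_mask(self, cohort: Cohort | str) -> np.ndarray:
        cohort = Cohort(cohort)
        return np.array([ind.cohort == cohort for ind in self.individuals], dtype=bool)

    def cohorts(self) -> list[Cohort]:
        seen: list[Cohort] = []
        for ind in self.individuals:
            if ind.cohort not in seen:
                seen.append(ind.cohort)
        return seen

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        inds = [ind for ind, keep in zip(self.individuals, mask) if keep]
        return GenotypeMatrix(inds, list(self.markers), self.calls[mask])

    def validate(self) -> None:
        if len({m.name for m in self.markers}) != len(self.markers):
            raise ValueError("marker names must be unique within a panel")
        if len({ind.id for ind in self.individuals}) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.calls, [0, 1, 2, 3])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[i, j]} for individual "
                f"{self.individuals[i].id!r} at marker {self.markers[j].name!r}"
            )
        nrbc = self.cohort_mask(Cohort.NRBC_ADULT_MALE)
        if nrbc.any() and (self.calls[nrbc] == Genotype.HOM_P1).any():
            # Possible only through genotyping artifacts: a true NR-BC
            # genotype is HET or HOM_P2 on every chromosome.
            warnings.warn(
                "NR-BC cohort contains HOM_P1 (AA) calls; true non-recombinant "
                "backcross genotypes are restricted to AB/BB, so these are "
                "genotyping artifacts",
                stacklevel=2,
            )

    # -- frames --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Serializable frame: metadata columns then one column per marker."""
        meta = pd.DataFrame(
            {
                "individual_id": [i.id for i in self.individuals],
                "cohort": [i.cohort.value for i in self.individuals],
                "family": [i.family for i in self.individuals],
                "sex": [i.sex.value for i in self.individuals],
            }
        )
        geno = pd.DataFrame(
            TOKENS[self.calls], columns=self.marker_names, index=meta.index
        )
        return pd.concat([meta, geno], axis=1)


_METADATA_COLUMNS = ("individual_id", "cohort", "family", "sex")


def read_genotype_table(
    path, marker_map: list[MarkerDef] | None = None
) -> GenotypeMatrix:
    """Read a genotype CSV into a validated :class:`GenotypeMatrix`.

    The file must have columns ``individual_id, cohort, family, sex``
    followed by one column per marker with cell tokens in
    {AA, AB, BB, NA}.  If *marker_map* is given, chromosome/position
    metadata is attached to the matching marker columns.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            raise GenotypeFormatError(f"missing mandatory column {col!r}")
    marker_cols = [c for c in df.columns if c not in _METADATA_COLUMNS]

    by_name = {m.name: m for m in marker_map} if marker_map else {}
    markers = [by_name.get(c, MarkerDef(c)) for c in marker_cols]

    individuals = []
    for row in df.itertuples(index=False):
        try:
            cohort = Cohort(row.cohort)
        except ValueError:
            raise GenotypeFormatError(
                f"unknown cohort label {row.cohort!r} for individual "
                f"{row.individual_id!r}"
            ) from None
        try:
            sex = Sex(row.sex)
        except ValueError:
            raise GenotypeFormatError(
                f"unknown sex label {row.sex!r} for individual {row.individual_id!r}"
            ) from None
        individuals.append(Individual(row.individual_id, cohort, row.family, sex))

    calls = np.empty((len(df), len(marker_cols)), dtype=np.int8)
    for j, col in enumerate(marker_cols):
        codes = df[col].map(_TOKEN_TO_CODE)
        if codes.isna().any():
            i = int(codes.isna().idxmax())
            raise GenotypeParseError(
                f"invalid genotype token {df[col].iloc[i]!r} at row {i} "
                f"(individual {df['individual_id'].iloc[i]!r}), marker {col!r}"
            )
        calls[:, j] = codes.to_numpy(dtype=np.int8)

    return GenotypeMatrix(individuals, markers, calls)


def write_genotype_table(gm: GenotypeMatrix, path) -> None:
    """Write the genotype CSV (stable column order, MISSING as NA)."""
    gm.to_frame().to_csv(path, index=False)


def read_marker_map(path) -> list[MarkerDef]:
    """Read a marker map TSV: marker, chromosome, position_cM, marker_class."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("marker", "chromosome", "position_cM", "marker_class"):
        if col not in df.columns:
            raise GenotypeFormatError(f"marker map: missing column {col!r}")
    return [
        MarkerDef(
            row.marker,
            chromosome=row.chromosome or None,
            position_cM=float(row.position_cM) if row.position_cM else None,
            marker_class=MarkerClass(row.marker_class),
        )
        for row in df.itertuples(index=False)
    ]


def write_marker_map(markers: list[MarkerDef], path) -> None:
    pd.DataFrame(
        {
            "marker": [m.name for m in markers],
            "chromosome": [m.chromosome or "" for m in markers],
            "position_cM": ["" if m.position_cM is None else m.position_cM for m in markers],
            "marker_class": [m.marker_class.value for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


def genotype_counts(
    gm: GenotypeMatrix, marker: str, cohort: Cohort | str
) -> GenotypeCounts:
    """Tally genotype calls for one marker over one cohort.

    Counts are conserved: het + hom_p1 + hom_p2 + missing equals the
    cohort size.
    """
    j = gm.marker_index(marker)
    mask = gm.cohort_mask(cohort)
    if not mask.any():
        raise ValueError(f"cohort {Cohort(cohort).value!r} is empty")
    col = gm.calls[mask, j]
    return GenotypeCounts(
        n_het=int((col == Genotype.HET).sum()),
        n_hom_p1=int((col == Genotype.HOM_P1).sum()),
        n_hom_p2=int((col == Genotype.HOM_P2).sum()),
        n_missing=int((col == Genotype.MISSING).sum()),
    )
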