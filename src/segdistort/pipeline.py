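"""End-to-end report assembly: mapping, distortion and epistasis scans.

`analyze` runs every applicable stage on a genotype matrix — per-cohort
two-point maps, the single-locus F2 distortion scans, the pooled
allele-ratio tests, the NR-BC chromosome-level scan, the inter-group
epistasis scan and the NR-BC LD scan — writes one TSV per result table
plus a JSON report, and returns the report.  Cohorts absent from the
matrix are marked absent rather than failing the run.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import pandas as pd

from .genotypes import Cohort, GenotypeMatrix
from .linkage import LinkageGroupMap, build_map, map_summary
from .distortion import allele_ratio_test, scan_f2, scan_nrbc
from .epistasis import scan_nrbc_ld, scan_pairs

__all__ = ["analyze", "maps_to_frame", "pairwise_to_frame"]

_F2_COHORTS = (Cohort.F2_NAUPLII, Cohort.F2_ADULT_MALE)


def maps_to_frame(maps: list[LinkageGroupMap]) -> pd.DataFrame:
    rows = []
    for g in maps:
        for order, (marker, pos) in enumerate(zip(g.markers, g.positions_cM)):
            rows.append(
                {"group_id": g.group_id, "marker": marker,
                 "position_cM": pos, "order": order}
            )
    return pd.DataFrame(rows)


def pairwise_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_a": [r.marker_a for r in results],
            "marker_b": [r.marker_b for r in results],
            "r_hat": [r.r_hat for r in results],
            "lod": [r.lod for r in results],
            "p_linkage": [r.p_linkage for r in results],
            "n_informative": [r.n_informative for r in results],
        }
    )


def _marker_groups(gm: GenotypeMatrix, maps: list[LinkageGroupMap] | None) -> dict[str, str]:
    """Physical chromosome assignment when known, else inferred groups."""
    if all(m.chromosome is not None for m in gm.markers):
        return {m.name: m.chromosome for m in gm.markers}
    if maps is None:
        raise ValueError("no chromosome assignments and no inferred map")
    return {m: g.group_id for g in maps for m in g.markers}


def analyze(
    gm: GenotypeMatrix,
    out_dir,
    sex_model: str = "symmetric",
    alpha_linkage: float = 0.001,
    class_mode: str = "ordered9",
    log=print,
) -> dict:
    """Run every analysis stage applicable to the matrix; write tables.

    Returns the report dict (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    present = gm.cohorts()
    report: dict = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "n_individuals": len(gm.individuals),
        "n_markers": len(gm.markers),
        "cohorts": [c.value for c in present],
        "parameters": {
            "sex_model": sex_model,
            "alpha_linkage": alpha_linkage,
            "class_mode": class_mode,
        },
        "files": [],
    }

    def write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        report["files"].append(name)

    maps_by_cohort: dict[Cohort, list[LinkageGroupMap]] = {}
    for cohort in present:
        if cohort not in _F2_COHORTS or len(gm.markers) < 2:
            continue
        log(f"[map] cohort={cohort.value} sex_model={sex_model} alpha={alpha_linkage}")
        maps, pairwise = build_map(gm, cohort, sex_model=sex_model, alpha=alpha_linkage)
        maps_by_cohort[cohort] = maps
        write(maps_to_frame(maps), f"map_{cohort.value}.tsv")
        write(pairwise_to_frame(pairwise), f"pairwise_{cohort.value}.tsv")
        try:
            ms = map_summary(maps)
            report[f"map_summary_{cohort.value}"] = {
                "n_groups": ms.n_groups,
                "n_singletons": ms.n_singletons,
                "total_length_cM": ms.total_length,
                "mean_spacing_cM": ms.d,
                "n_assigned_markers": ms.n,
                "corrected_length_cM": ms.corrected_length,
                "coverage": ms.coverage,
            }
        except ValueError:
            report[f"map_summary_{cohort.value}"] = None

    for cohort in _F2_COHORTS:
        key = f"distortion_{cohort.value}"
        if cohort not in present:
            report[key] = None
            continue
        scan = scan_f2(gm, cohort)
        log(
            f"[distortion] cohort={cohort.value} "
            f"bonferroni_threshold={scan.bonferroni_threshold:.5g}"
        )
        write(scan.to_frame(), f"{key}.tsv")
        report[key] = scan.summary()
        ar = allele_ratio_test(gm, cohort)
        report[f"allele_ratio_{cohort.value}"] = {
            "n_p1_alleles": ar.n_p1_alleles,
            "n_p2_alleles": ar.n_p2_alleles,
            "chi2": ar.chi2,
            "p": ar.p,
            "direction": ar.direction,
        }

    for cohort in _F2_COHORTS:
        key = f"epistasis_{cohort.value}"
        if cohort not in present:
            report[key] = None
            continue
        groups = _marker_groups(gm, maps_by_cohort.get(cohort))
        scan = scan_pairs(gm, cohort, groups, class_mode=class_mode)
        log(
            f"[epistasis] cohort={cohort.value} groups={scan.n_groups} "
            f"bonferroni_denominator={scan.bonferroni_denominator}"
        )
        write(scan.to_frame(), f"{key}.tsv")
        report[key] = scan.summary()

    if Cohort.NRBC_ADULT_MALE in present:
        scan = scan_nrbc(gm)
        log(f"[nrbc] chromosome scan bonferroni_threshold={scan.bonferroni_threshold:.5g}")
        write(scan.to_frame(), "distortion_nrbc.tsv")
        report["distortion_nrbc"] = scan.summary()
        ld = scan_nrbc_ld(gm)
        write(
            pd.DataFrame(
                {
                    "chrom_a": [r.chrom_a for r in ld],
                    "chrom_b": [r.chrom_b for r in ld],
                    "n_het_het": [r.counts[0, 0] for r in ld],
                    "n_het_hom": [r.counts[0, 1] for r in ld],
                    "n_hom_het": [r.counts[1, 0] for r in ld],
                    "n_hom_hom": [r.counts[1, 1] for r in ld],
                    "chi2": [r.chi2 for r in ld],
                    "p": [r.p for r in ld],
                    "testable": [r.testable for r in ld],
                }
            ),
            "ld_nrbc.tsv",
        )
        report["ld_nrbc"] = {
            "n_pairs": len(ld),
            "n_p05": sum(r.testable and r.p < 0.05 for r in ld),
            "n_untestable": sum(not r.testable for r in ld),
        }
    else:
        report["distortion_nrbc"] = None
        report["ld_nrbc"] = None

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    report_files = list(report["files"]) + ["report.json"]
    assert all((out / f).exists() for f in report_files)
    return report
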