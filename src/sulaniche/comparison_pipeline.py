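"""Orchestration of the full niche-comparison grid.

The default grid mirrors the study design for two sympatric species
sampled in two tissues (whole blood = breeding period, body feathers =
non-breeding period):

* inter-specific comparison within each tissue (sexes pooled);
* female vs male within each species × tissue;
* breeding vs non-breeding within each species (whole-blood values
  standardized to feather-equivalents first, sexes pooled).

With both species, both sexes, and both tissues present this yields 8
comparisons.  Each non-skipped comparison gets two fitted ellipses, an
ellipse-overlap result, and the two permutation tests (niche width and
niche position).  Additionally, bulk per-isotope means are compared by
Tukey HSD over the four species × sex cells within each tissue, at a
family-wise alpha of 0.05.

Groups smaller than the minimum size are emitted with a skip flag
rather than failing the run.  Sexed analyses exclude samples of
unknown sex; species-level (pooled) analyses include them.  Years are
pooled throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .io_tables import RunConfig, read_diet_table, read_isotope_table, write_report
from .niche_geometry import (
    EllipseSummary,
    OverlapResult,
    fit_ellipse,
    overlap_index,
    scale_ellipse,
)
from .permutation_tests import (
    PermutationTestResult,
    centroid_distance_test,
    dispersion_difference_test,
)
from .tissue_standardization import DEFAULT_COEFFICIENTS, blood_to_feather
from .diet_analysis import compare_diets

logger = logging.getLogger("sulaniche")

PERIOD_BY_TISSUE = {"whole_blood": "breeding", "body_feather": "non_breeding"}

_SCALE_ARGS = {
    "standard": ("standard", None),
    "seac": ("seac", None),
    "p50": ("probability", 0.50),
    "p95": ("probability", 0.95),
}


class GroupKey(NamedTuple):
    """(species, sex-or-'pooled', tissue) identifying one niche group."""

    species: str
    sex: str
    tissue: str

    @property
    def period(self) -> str:
        return PERIOD_BY_TISSUE.get(self.tissue, "unknown")

    def label(self) -> str:
        return f"{self.species}/{self.sex}/{self.tissue}"


@dataclass(frozen=True)
class ComparisonSpec:
    """One planned pairwise comparison of the grid."""

    name: str
    key_a: GroupKey
    key_b: GroupKey
    transform: str = "none"      # 'none' | 'blood_to_feather_a'
    analyses: tuple = ("dispersion", "centroid", "overlap")
    skip: bool = False
    skip_reason: str = ""


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    n_a: int = 0
    n_b: int = 0
    ellipse_a: EllipseSummary | None = None
    ellipse_b: EllipseSummary | None = None
    overlap: OverlapResult | None = None
    dispersion: PermutationTestResult | None = None
    centroid: PermutationTestResult | None = None
    note: str = ""


def extract_group(samples, key: GroupKey) -> np.ndarray:
    """(n, 2) array of (δ13C, δ15N) for one group key.

    ``sex='pooled'`` takes every sample of the species × tissue cell,
    including unknown-sex birds; a named sex matches exactly.
    """
    sel = [
        (s.d13c, s.d15n)
        for s in samples
        if s.species == key.species
        and s.tissue == key.tissue
        and (key.sex == "pooled" or s.sex == key.sex)
    ]
    return np.asarray(sel, dtype=float).reshape(-1, 2)


def build_default_grid(samples, min_n: int = 3) -> list[ComparisonSpec]:
    """Emit the study's comparison grid for the given dataset.

    Undersized or absent groups yield specs with ``skip=True`` and a
    reason, never a failure.
    """
    samples = list(samples)
    species = sorted({s.species for s in samples})
    tissues = [t for t in ("whole_blood", "body_feather")
               if any(s.tissue == t for s in samples)]
    specs: list[ComparisonSpec] = []

    def n_of(key: GroupKey) -> int:
        return extract_group(samples, key).shape[0]

    def make(name, key_a, key_b, transform="none"):
        n_a, n_b = n_of(key_a), n_of(key_b)
        skip = n_a < min_n or n_b < min_n
        reason = ""
        if skip:
            small = key_a.label() if n_a < min_n else key_b.label()
            reason = f"group {small} has n < {min_n}"
        return ComparisonSpec(name=name, key_a=key_a, key_b=key_b,
                              transform=transform, skip=skip, skip_reason=reason)

    # Inter-specific, sexes pooled, per tissue.
    for tissue in ("whole_blood", "body_feather"):
        if len(species) >= 2 and tissue in tissues:
            specs.append(make(
                f"inter_specific_{tissue}",
                GroupKey(species[0], "pooled", tissue),
                GroupKey(species[1], "pooled", tissue),
            ))
        else:
            reason = ("tissue absent from dataset" if tissue not in tissues
                      else "only one species present")
            specs.append(ComparisonSpec(
                name=f"inter_specific_{tissue}",
                key_a=GroupKey(species[0], "pooled", tissue),
                key_b=GroupKey(species[-1], "pooled", tissue),
                skip=True, skip_reason=reason,
            ))

    # Intra-specific (female vs male), per species x tissue.
    for sp in species:
        for tissue in ("whole_blood", "body_feather"):
            if tissue in tissues:
                specs.append(make(
                    f"{sp}_female_vs_male_{tissue}",
                    GroupKey(sp, "female", tissue),
                    GroupKey(sp, "male", tissue),
                ))
            else:
                specs.append(ComparisonSpec(
                    name=f"{sp}_female_vs_male_{tissue}",
                    key_a=GroupKey(sp, "female", tissue),
                    key_b=GroupKey(sp, "male", tissue),
                    skip=True, skip_reason="tissue absent from dataset",
                ))

    # Breeding (standardized blood) vs non-breeding (feathers), per species.
    for sp in species:
        key_a = GroupKey(sp, "pooled", "whole_blood")
        key_b = GroupKey(sp, "pooled", "body_feather")
        if "whole_blood" in tissues and "body_feather" in tissues:
            specs.append(make(f"{sp}_breeding_vs_non_breeding", key_a, key_b,
                              transform="blood_to_feather_a"))
        else:
            specs.append(ComparisonSpec(
                name=f"{sp}_breeding_vs_non_breeding", key_a=key_a, key_b=key_b,
                transform="blood_to_feather_a",
                skip=True, skip_reason="tissue absent from dataset",
            ))
    return specs


def per_isotope_pairwise(values_by_group, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise mean comparisons over >= 2 labeled groups.

    One one-way layout over the provided groups; returns a frame with
    adjusted p-values for every pair at family-wise ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    pooled_within = np.concatenate([v - v.mean() for v in groups.values()])
    if np.allclose(pooled_within, 0.0):
        raise ValueError("zero within-group variance: Tukey HSD undefined")
    labels = np.concatenate([[name] * v.size for name, v in sorted(groups.items())])
    endog = np.concatenate([v for _, v in sorted(groups.items())])
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": res.meandiffs,
        "p_adj": res.pvalues,
        "reject": res.reject,
    })


@dataclass
class AnalysisReport:
    """All per-comparison results plus run metadata, writable as tables."""

    comparisons: list
    tukey: pd.DataFrame
    metadata: dict
    diet: object | None = None

    def to_frames(self) -> dict:
        rows = []
        for r in self.comparisons:
            spec = r.spec
            row = {
                "comparison": spec.name,
                "group_a": spec.key_a.label(),
                "group_b": spec.key_b.label(),
                "transform": spec.transform,
                "skipped": spec.skip,
                "skip_reason": spec.skip_reason,
                "n_a": r.n_a, "n_b": r.n_b,
            }
            if r.ellipse_a is not None:
                row.update(sea_a=r.ellipse_a.sea, seac_a=r.ellipse_a.seac,
                           centroid_a_d13c=r.ellipse_a.centroid[0],
                           centroid_a_d15n=r.ellipse_a.centroid[1])
            if r.ellipse_b is not None:
                row.update(sea_b=r.ellipse_b.sea, seac_b=r.ellipse_b.seac,
                           centroid_b_d13c=r.ellipse_b.centroid[0],
                           centroid_b_d15n=r.ellipse_b.centroid[1])
            if r.overlap is not None:
                row.update(overlap_area=r.overlap.intersection,
                           overlap_jaccard=r.overlap.jaccard,
                           overlap_percent=r.overlap.percent)
            if r.dispersion is not None:
                row.update(dispersion_observed=r.dispersion.observed,
                           dispersion_p=r.dispersion.p_value)
            if r.centroid is not None:
                row.update(centroid_observed=r.centroid.observed,
                           centroid_p=r.centroid.p_value)
            if r.note:
                row["note"] = r.note
            rows.append(row)
        frames = {"comparisons": pd.DataFrame(rows), "tukey": self.tukey}
        if self.diet is not None:
            frames.update(self.diet.to_frames())
        return frames

    def summary(self) -> dict:
        comps = {}
        for r in self.comparisons:
            entry = {"skipped": bool(r.spec.skip)}
            if r.spec.skip:
                entry["skip_reason"] = r.spec.skip_reason
            else:
                entry.update({
                    "n_a": int(r.n_a), "n_b": int(r.n_b),
                    "overlap_jaccard": None if r.overlap is None else round(r.overlap.jaccard, 4),
                    "dispersion_observed": None if r.dispersion is None else float(r.dispersion.observed),
                    "dispersion_p": None if r.dispersion is None else float(r.dispersion.p_value),
                    "centroid_observed": None if r.centroid is None else float(r.centroid.observed),
                    "centroid_p": None if r.centroid is None else float(r.centroid.p_value),
                })
            comps[r.spec.name] = entry
        out = {"metadata": dict(self.metadata), "comparisons": comps}
        if self.diet is not None:
            out["diet"] = {
                "chi2": {"statistic": float(self.diet.chi2[0]),
                         "df": int(self.diet.chi2[1]), "p": float(self.diet.chi2[2])},
                "foodload_t": {k: float(self.diet.foodload_t[k]) for k in ("t", "df", "p")},
                "length_t": {k: float(self.diet.length_t[k]) for k in ("t", "df", "p")},
            }
        return out


def _comparison_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2^31) from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_comparisons(samples, config: RunConfig = RunConfig(),
                    coeffs=DEFAULT_COEFFICIENTS) -> AnalysisReport:
    """Execute the default comparison grid on an isotope dataset."""
    samples = sorted(samples, key=lambda s: s.sample_id)
    grid = build_default_grid(samples, min_n=config.min_group_n)
    seeds = _comparison_seeds(config.seed, 2 * len(grid))
    mode, p = _SCALE_ARGS[config.ellipse_scale]

    results = []
    for i, spec in enumerate(grid):
        res = ComparisonResult(spec=spec)
        if spec.skip:
            results.append(res)
            continue
        xy_a = extract_group(samples, spec.key_a)
        xy_b = extract_group(samples, spec.key_b)
        if spec.transform == "blood_to_feather_a":
            c, n_vals = blood_to_feather(xy_a[:, 0], xy_a[:, 1], coeffs)
            xy_a = np.column_stack([c, n_vals])
        res.n_a, res.n_b = xy_a.shape[0], xy_b.shape[0]
        res.ellipse_a = fit_ellipse(xy_a)
        res.ellipse_b = fit_ellipse(xy_b)
        if res.ellipse_a.degenerate or res.ellipse_b.degenerate:
            res.note = "degenerate ellipse: overlap not computed"
        else:
            se_a = scale_ellipse(res.ellipse_a, mode, p=p)
            se_b = scale_ellipse(res.ellipse_b, mode, p=p)
            res.overlap = overlap_index(se_a, se_b, n_vertices=config.n_vertices)
        res.dispersion = dispersion_difference_test(
            xy_a, xy_b, n_perm=config.n_perm, seed=seeds[2 * i])
        res.centroid = centroid_distance_test(
            xy_a, xy_b, n_perm=config.n_perm, seed=seeds[2 * i + 1])
        results.append(res)

    tukey = _tissue_tukey(samples, alpha=config.alpha)
    metadata = {
        "seed": int(config.seed), "n_perm": int(config.n_perm),
        "ellipse_scale": config.ellipse_scale,
        "min_group_n": int(config.min_group_n),
        "software_version": __version__,
    }
    return AnalysisReport(comparisons=results, tukey=tukey, metadata=metadata)


def _tissue_tukey(samples, alpha: float) -> pd.DataFrame:
    """Tukey HSD per tissue and isotope over the species × sex cells."""
    frames = []
    for tissue in ("whole_blood", "body_feather"):
        cells = {}
        for s in samples:
            if s.tissue != tissue or s.sex not in ("female", "male"):
                continue
            cells.setdefault(f"{s.species}_{s.sex}", []).append((s.d13c, s.d15n))
        cells = {k: np.asarray(v) for k, v in cells.items() if len(v) >= 2}
        if len(cells) < 2:
            continue
        for j, isotope in enumerate(("d13c", "d15n")):
            try:
                frame = per_isotope_pairwise(
                    {k: v[:, j] for k, v in cells.items()}, alpha=alpha)
            except ValueError as exc:
                logger.warning("Tukey HSD skipped for %s/%s: %s", tissue, isotope, exc)
                continue
            frame.insert(0, "isotope", isotope)
            frame.insert(0, "tissue", tissue)
            frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["tissue", "isotope", "group1", "group2", "meandiff", "p_adj", "reject"])
    return pd.concat(frames, ignore_index=True)


def run(isotopes, diet=None, config: RunConfig = RunConfig(),
        coeffs=DEFAULT_COEFFICIENTS, out_dir=None,
        column_map=None) -> AnalysisReport:
    """Full pipeline: read inputs, run the grid, optionally write a report.

    ``isotopes`` and ``diet`` may be file paths or already-validated
    sample collections.  Fully reproducible given ``config.seed``.
    """
    if isinstance(isotopes, (str, bytes)) or hasattr(isotopes, "__fspath__"):
        isotopes = read_isotope_table(isotopes, column_map=column_map)
    report = run_comparisons(isotopes, config=config, coeffs=coeffs)
    if diet is not None:
        if isinstance(diet, (str, bytes)) or hasattr(diet, "__fspath__"):
            diet = read_diet_table(diet)
        report.diet = compare_diets(diet)
    if out_dir is not None:
        write_report(report, out_dir)
    return report
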