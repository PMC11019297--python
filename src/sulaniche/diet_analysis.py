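"""Diet descriptors and between-species diet comparisons.

From a collection of regurgitate samples the module computes:

* **frequency of occurrence (FO%)** — per prey family, the percentage
  of samples containing at least one item of that family (presence,
  not abundance: duplicate items within a sample count once);
* **items-per-sample** summaries (mean ± sd per species);
* a **Pearson χ² homogeneity test** of family composition between
  species (item counts, no continuity correction, df = (r−1)(c−1));
* **two-sample t-tests** on food-load mass and on the length of prey
  items that were complete from head to tail (Welch by default, pooled
  variance available for replication of analyses that used it).

All prey lengths are treated as a single declared unit (centimeters);
the module never mixes units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("sulaniche")


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero row or column."""


def frequency_of_occurrence(samples) -> pd.DataFrame:
    """FO% table: species (rows) × prey family (columns), values in [0, 100].

    FO% = 100 × (samples containing >= 1 item of the family) / samples,
    computed per species.  Multiple items of one family within a sample
    count once.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("frequency of occurrence of an empty collection")
    species = sorted({s.species for s in samples})
    families = sorted({item.family for s in samples for item in s.items})
    table = pd.DataFrame(0.0, index=species, columns=families)
    counts = {sp: 0 for sp in species}
    for s in samples:
        counts[s.species] += 1
        for fam in {item.family for item in s.items}:
            table.loc[s.species, fam] += 1
    for sp in species:
        table.loc[sp] = 100.0 * table.loc[sp] / counts[sp]
    table.index.name = "species"
    return table


def items_per_sample(samples) -> pd.DataFrame:
    """Mean ± sd (and n) of the number of prey items per sample, by species."""
    samples = list(samples)
    if not samples:
        raise ValueError("items per sample of an empty collection")
    rows = []
    for sp in sorted({s.species for s in samples}):
        k = np.array([len(s.items) for s in samples if s.species == sp], dtype=float)
        rows.append({
            "species": sp, "n_samples": int(k.size),
            "items_mean": float(k.mean()),
            "items_sd": float(k.std(ddof=1)) if k.size > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


def composition_counts(samples) -> pd.DataFrame:
    """Species × family table of prey-item counts."""
    samples = list(samples)
    species = sorted({s.species for s in samples})
    families = sorted({item.family for s in samples for item in s.items})
    table = pd.DataFrame(0, index=species, columns=families)
    for s in samples:
        for item in s.items:
            table.loc[s.species, item.family] += 1
    table.index.name = "species"
    return table


def composition_chi2(counts) -> tuple[float, int, float]:
    """Pearson χ² homogeneity test on a species × family count table.

    No continuity correction; df = (rows − 1)(columns − 1).  Cells with
    expected count < 5 are flagged in the log (the asymptotic p-value
    is then approximate).  Returns ``(statistic, df, p)``.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must have >= 2 rows and columns")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise DegenerateTableError("contingency table has an all-zero row or column")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    n_small = int(np.count_nonzero(expected < 5))
    if n_small:
        logger.warning(
            "composition chi2: %d cell(s) with expected count < 5; "
            "asymptotic p-value is approximate", n_small,
        )
    return float(stat), int(df), float(p)


def two_sample_t(a, b, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    ``variant='welch'`` uses the Welch–Satterthwaite degrees of
    freedom; ``variant='pooled'`` assumes equal variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("t statistic undefined: zero variance in both groups with equal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class DietComparisonReport:
    """The full set of between-species diet statistics."""

    fo_table: pd.DataFrame
    items_per_sample: pd.DataFrame
    chi2: tuple                 # (statistic, df, p)
    foodload_t: dict            # t, df, p + per-species mean ± sd (g)
    length_t: dict              # t, df, p + per-species mean ± sd (cm), complete-item counts

    def to_frames(self) -> dict:
        fo = self.fo_table.reset_index()
        tests = pd.DataFrame([
            {"test": "composition_chi2", "statistic": self.chi2[0],
             "df": self.chi2[1], "p": self.chi2[2]},
            {"test": "foodload_t", "statistic": self.foodload_t["t"],
             "df": self.foodload_t["df"], "p": self.foodload_t["p"]},
            {"test": "length_t", "statistic": self.length_t["t"],
             "df": self.length_t["df"], "p": self.length_t["p"]},
        ])
        return {
            "diet_frequency_of_occurrence": fo,
            "diet_items_per_sample": self.items_per_sample,
            "diet_tests": tests,
        }


def _group_summary(values_by_species) -> dict:
    out = {}
    for sp, vals in sorted(values_by_species.items()):
        v = np.asarray(vals, dtype=float)
        out[sp] = {
            "n": int(v.size),
            "mean": float(v.mean()) if v.size else float("nan"),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        }
    return out


def compare_diets(samples, t_variant: str = "welch") -> DietComparisonReport:
    """Run the full diet comparison between exactly two species.

    Food-load mass uses one value per sample; the prey-length test uses
    only items flagged complete (head-to-tail) with a recorded length.
    """
    samples = list(samples)
    species = sorted({s.species for s in samples})
    if len(species) != 2:
        raise ValueError(f"diet comparison needs exactly 2 species (got {len(species)})")
    sp_a, sp_b = species

    fo = frequency_of_occurrence(samples)
    ips = items_per_sample(samples)
    chi2_res = composition_chi2(composition_counts(samples))

    masses = {sp: [s.total_mass_g for s in samples if s.species == sp] for sp in species}
    t, df, p = two_sample_t(masses[sp_a], masses[sp_b], variant=t_variant)
    foodload = {"t": t, "df": df, "p": p, "by_species": _group_summary(masses)}

    lengths = {
        sp: [item.length_cm for s in samples if s.species == sp
             for item in s.items if item.complete and item.length_cm is not None]
        for sp in species
    }
    t, df, p = two_sample_t(lengths[sp_a], lengths[sp_b], variant=t_variant)
    length = {"t": t, "df": df, "p": p, "by_species": _group_summary(lengths)}

    return DietComparisonReport(
        fo_table=fo, items_per_sample=ips, chi2=chi2_res,
        foodload_t=foodload, length_t=length,
    )
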