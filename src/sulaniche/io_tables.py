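"""Reading, validation and report output for isotope and diet tables.

The package works from two tidy comma-delimited inputs:

* an **isotope table** with one row per individual tissue sample
  (``sample_id, species, sex, tissue, year, d13c, d15n, c_n_ratio``),
  δ values in ‰ (δ13C vs V-PDB, δ15N vs atmospheric N2);
* a **diet table** in long format with one row per prey item
  (``sample_id, species, total_mass_g, family, length_cm, complete``),
  where ``total_mass_g`` is the food-load mass of the whole regurgitate
  and is repeated on every row of the sample.

Validation enforces a controlled vocabulary for the grouping labels and
the lipid screening rule: whole-tissue δ13C needs no mathematical lipid
correction only while the C:N mass ratio stays below 4, so rows at or
above that threshold are retained but flagged in the run log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("sulaniche")

#: C:N mass ratio at and above which lipid correction of δ13C is advised.
LIPID_CN_THRESHOLD = 4.0

ISOTOPE_COLUMNS = ("sample_id", "species", "sex", "tissue", "year", "d13c", "d15n")
DIET_COLUMNS = ("sample_id", "species", "total_mass_g", "family", "length_cm", "complete")


class TableError(ValueError):
    """Base class for tabular-input problems."""


class SchemaError(TableError):
    """A required column is missing from the input table."""


class RowParseError(TableError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class VocabularyError(TableError):
    """A grouping label is not in the declared controlled vocabulary."""


class IntegrityError(TableError):
    """Duplicate or contradictory rows in the diet table."""


class ValidationError(TableError):
    """A value violates a domain invariant (e.g. negative mass)."""


@dataclass(frozen=True)
class Vocabulary:
    """Controlled vocabulary for the categorical grouping labels."""

    species: frozenset = frozenset({"masked", "red_footed"})
    sexes: frozenset = frozenset({"female", "male", "unknown"})
    tissues: frozenset = frozenset({"whole_blood", "body_feather"})


DEFAULT_VOCABULARY = Vocabulary()


@dataclass(frozen=True)
class IsotopeSample:
    """One individual's tissue measurement in bivariate δ-space."""

    sample_id: str
    species: str
    sex: str
    tissue: str
    year: int
    d13c: float
    d15n: float
    c_n_ratio: float | None = None

    def __post_init__(self):
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ValidationError(
                f"sample {self.sample_id}: d13c and d15n must be finite"
            )
        if self.c_n_ratio is not None:
            if not math.isfinite(self.c_n_ratio) or self.c_n_ratio <= 0:
                raise ValidationError(
                    f"sample {self.sample_id}: c_n_ratio must be a positive number"
                )


@dataclass(frozen=True)
class PreyItem:
    """A single prey item recovered from a regurgitate.

    ``length_cm`` is recorded for every measurable item, but comparisons
    between groups only use items with ``complete=True`` (head-to-tail).
    """

    family: str
    length_cm: float | None = None
    complete: bool = False

    def __post_init__(self):
        if self.length_cm is not None:
            if not math.isfinite(self.length_cm) or self.length_cm <= 0:
                raise ValidationError("prey length_cm must be > 0 when present")


@dataclass(frozen=True)
class DietSample:
    """One regurgitate: total food-load mass plus its prey items."""

    sample_id: str
    species: str
    total_mass_g: float
    items: tuple = ()

    def __post_init__(self):
        if not math.isfinite(self.total_mass_g) or self.total_mass_g < 0:
            raise ValidationError(
                f"diet sample {self.sample_id}: total_mass_g must be finite and >= 0"
            )


@dataclass(frozen=True)
class RunConfig:
    """Run configuration shared by the comparison pipeline and CLI.

    seed            master seed for every stochastic step
    n_perm          permutations per test (minimum 99)
    ellipse_scale   'standard' | 'seac' | 'p50' | 'p95'
    min_group_n     groups below this size are skipped, not failed
    n_vertices      polygon resolution for ellipse intersection
    alpha           significance threshold
    """

    seed: int = 1
    n_perm: int = 9999
    ellipse_scale: str = "seac"
    min_group_n: int = 3
    n_vertices: int = 720
    alpha: float = 0.05


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown configuration key(s): {', '.join(unknown)}")
    return RunConfig(**raw)


def _check_labels(row_idx, species, sex, tissue, vocab: Vocabulary):
    for value, pool, name in (
        (species, vocab.species, "species"),
        (sex, vocab.sexes, "sex"),
        (tissue, vocab.tissues, "tissue"),
    ):
        if value not in pool:
            raise VocabularyError(
                f"row {row_idx}: {name} label {value!r} not in vocabulary "
                f"{sorted(pool)}"
            )


def read_isotope_table(
    path,
    vocab: Vocabulary = DEFAULT_VOCABULARY,
    column_map: Mapping[str, str] | None = None,
) -> list[IsotopeSample]:
    """Read and validate a tidy isotope table.

    ``column_map`` renames externally named columns (e.g. a deposited
    data set's headers) onto the canonical names before validation.
    Rows with C:N ratio >= 4 are retained but a lipid-correction
    advisory is written to the run log; rows without a C:N ratio leave
    the lipid rule unevaluated, which is also logged.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    has_cn = "c_n_ratio" in df.columns
    samples: list[IsotopeSample] = []
    n_unevaluated = 0
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            d13c = float(getattr(row, "d13c"))
            d15n = float(getattr(row, "d15n"))
            year = int(getattr(row, "year"))
        except (TypeError, ValueError) as exc:
            raise RowParseError(i, f"non-numeric value ({exc})") from None
        if not (math.isfinite(d13c) and math.isfinite(d15n)):
            raise RowParseError(i, "d13c/d15n must be finite")
        species = str(getattr(row, "species"))
        sex = str(getattr(row, "sex"))
        tissue = str(getattr(row, "tissue"))
        _check_labels(i, species, sex, tissue, vocab)

        cn = None
        if has_cn:
            raw_cn = getattr(row, "c_n_ratio")
            if raw_cn is not None and not (isinstance(raw_cn, float) and math.isnan(raw_cn)):
                try:
                    cn = float(raw_cn)
                except (TypeError, ValueError):
                    raise RowParseError(i, "non-numeric c_n_ratio") from None
        if cn is None:
            n_unevaluated += 1
        elif cn >= LIPID_CN_THRESHOLD:
            logger.warning(
                "row %d (%s): C:N ratio %.3g >= %.3g - lipid-correction advised",
                i, getattr(row, "sample_id"), cn, LIPID_CN_THRESHOLD,
            )
        try:
            samples.append(
                IsotopeSample(
                    sample_id=str(getattr(row, "sample_id")),
                    species=species, sex=sex, tissue=tissue,
                    year=year, d13c=d13c, d15n=d15n, c_n_ratio=cn,
                )
            )
        except ValidationError as exc:
            raise RowParseError(i, str(exc)) from None
    if n_unevaluated:
        logger.info(
            "lipid rule unevaluated for %d sample(s) without c_n_ratio",
            n_unevaluated,
        )
    return samples


def isotopes_to_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id, "species": s.species, "sex": s.sex,
            "tissue": s.tissue, "year": s.year, "d13c": s.d13c,
            "d15n": s.d15n, "c_n_ratio": s.c_n_ratio,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(ISOTOPE_COLUMNS) + ["c_n_ratio"])


def write_isotope_table(samples: Iterable[IsotopeSample], path) -> None:
    isotopes_to_frame(samples).to_csv(path, index=False)


def read_diet_table(path) -> list[DietSample]:
    """Read a long-format diet table, grouping prey items by sample.

    A row with an empty ``family`` denotes a weighed sample with no
    identifiable items.  An optional ``item_index`` column, when
    present, must be unique within each sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "species", "total_mass_g") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    if "item_index" in df.columns:
        dup = df.dropna(subset=["item_index"]).duplicated(
            subset=["sample_id", "item_index"]
        )
        if dup.any():
            first = df.loc[dup[dup].index[0]]
            raise IntegrityError(
                f"duplicated (sample_id, item_index) = "
                f"({first['sample_id']}, {first['item_index']})"
            )

    samples: list[DietSample] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        species = set(grp["species"].astype(str))
        if len(species) > 1:
            raise IntegrityError(f"sample {sample_id}: conflicting species labels")
        masses = set(round(float(m), 9) for m in grp["total_mass_g"])
        if len(masses) > 1:
            raise IntegrityError(f"sample {sample_id}: conflicting total_mass_g")
        mass = float(grp["total_mass_g"].iloc[0])
        if not math.isfinite(mass) or mass < 0:
            raise ValidationError(
                f"sample {sample_id}: total_mass_g must be finite and >= 0"
            )
        items = []
        for _, row in grp.iterrows():
            family = row.get("family")
            if family is None or (isinstance(family, float) and math.isnan(family)) or str(family) == "":
                continue
            length = row.get("length_cm")
            if length is None or (isinstance(length, float) and math.isnan(length)):
                length = None
            else:
                length = float(length)
            complete = _parse_bool(row.get("complete"))
            items.append(PreyItem(family=str(family), length_cm=length, complete=complete))
        samples.append(
            DietSample(
                sample_id=str(sample_id), species=str(grp["species"].iloc[0]),
                total_mass_g=mass, items=tuple(items),
            )
        )
    return samples


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f", ""}:
        return False
    raise ValidationError(f"cannot parse completeness flag {value!r}")


def diet_to_frame(samples: Iterable[DietSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        if not s.items:
            rows.append(
                {"sample_id": s.sample_id, "species": s.species,
                 "total_mass_g": s.total_mass_g, "family": "",
                 "length_cm": None, "complete": False, "item_index": 0}
            )
        for j, item in enumerate(s.items):
            rows.append(
                {"sample_id": s.sample_id, "species": s.species,
                 "total_mass_g": s.total_mass_g, "family": item.family,
                 "length_cm": item.length_cm, "complete": item.complete,
                 "item_index": j}
            )
    return pd.DataFrame(rows, columns=list(DIET_COLUMNS) + ["item_index"])


def write_diet_table(samples: Iterable[DietSample], path) -> None:
    diet_to_frame(samples).to_csv(path, index=False)


def write_report(report, out_dir) -> list[Path]:
    """Write an analysis report as delimited tables plus a YAML summary.

    ``report`` provides ``to_frames() -> {name: DataFrame}`` and
    ``summary() -> dict``.  Output is deterministic: identical inputs
    and seeds reproduce byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out}: {exc}") from exc
    written = []
    for name in sorted(report.to_frames()):
        frame = report.to_frames()[name]
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    summary_path = out / "summary.yaml"
    summary_path.write_text(yaml.safe_dump(report.summary(), sort_keys=True))
    written.append(summary_path)
    return written
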