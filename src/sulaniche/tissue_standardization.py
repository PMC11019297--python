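"""Blood-to-feather standardization of δ13C and δ15N.

Whole blood is isotopically impoverished in 13C and 15N relative to
feathers, so comparing a breeding-season niche (whole blood) with a
non-breeding niche (body feathers) requires putting blood values on a
feather-equivalent scale.  Each axis is transformed by its own linear
map:

    δ13C_feather = 0.972 δ13C_blood + 0.962
    δ15N_feather = 1.014 δ15N_blood + 0.447

The coefficient standard errors (±0.020 and ±0.414 for carbon, ±0.056
and ±0.414 for nitrogen) are carried as metadata but not propagated
into downstream uncertainty; the analysis uses the point estimates.
Feather samples are never transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TissueUsageError(ValueError):
    """Standardization applied to a sample that is not whole blood."""


@dataclass(frozen=True)
class StandardizationCoefficients:
    """Per-axis linear blood→feather conversion coefficients.

    Slopes are dimensionless; intercepts are in ‰.  Slopes must be
    positive so the transform is monotone on each axis.
    """

    slope_c: float = 0.972
    intercept_c: float = 0.962
    slope_c_se: float = 0.020
    intercept_c_se: float = 0.414
    slope_n: float = 1.014
    intercept_n: float = 0.447
    slope_n_se: float = 0.056
    intercept_n_se: float = 0.414

    def __post_init__(self):
        if self.slope_c <= 0 or self.slope_n <= 0:
            raise ValueError("standardization slopes must be > 0")


DEFAULT_COEFFICIENTS = StandardizationCoefficients()


def blood_to_feather(d13c_blood, d15n_blood,
                     coeffs: StandardizationCoefficients = DEFAULT_COEFFICIENTS):
    """Convert whole-blood δ values (‰) to feather-equivalent values (‰).

    Accepts scalars or arrays; each axis is transformed independently
    by its own linear map.  Returns ``(d13c_feather, d15n_feather)``.
    """
    d13c = np.asarray(d13c_blood, dtype=float)
    d15n = np.asarray(d15n_blood, dtype=float)
    if not (np.all(np.isfinite(d13c)) and np.all(np.isfinite(d15n))):
        raise ValueError("blood δ values must be finite")
    out_c = coeffs.slope_c * d13c + coeffs.intercept_c
    out_n = coeffs.slope_n * d15n + coeffs.intercept_n
    if np.ndim(d13c_blood) == 0 and np.ndim(d15n_blood) == 0:
        return float(out_c), float(out_n)
    return out_c, out_n


def standardize_sample(sample, coeffs: StandardizationCoefficients = DEFAULT_COEFFICIENTS):
    """Return a feather-equivalent copy of a whole-blood IsotopeSample.

    Raises :class:`TissueUsageError` for any other tissue: feather
    values are already on the feather scale and must not be transformed.
    """
    from dataclasses import replace

    if sample.tissue != "whole_blood":
        raise TissueUsageError(
            f"sample {sample.sample_id}: blood_to_feather applies only to "
            f"whole_blood (got {sample.tissue!r})"
        )
    d13c, d15n = blood_to_feather(sample.d13c, sample.d15n, coeffs)
    return replace(sample, d13c=d13c, d15n=d15n)


def standardize_blood_samples(samples, coeffs: StandardizationCoefficients = DEFAULT_COEFFICIENTS):
    """Standardize every whole-blood sample in a collection.

    Non-blood samples pass through unchanged (the pipeline only ever
    transforms the blood side of a breeding vs non-breeding comparison).
    """
    return [
        standardize_sample(s, coeffs) if s.tissue == "whole_blood" else s
        for s in samples
    ]
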