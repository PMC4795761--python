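"""Trait estimation from intertegular distance (IT) and family.

The core relationship is the allometric power function

    Y = a_family * IT^b        (ln Y = ln a_family + b * ln IT)

with Y a mouthpart length in mm, IT the intertegular distance in mm,
``a_family`` a family-specific coefficient and ``b`` the scaling exponent
(shared across families for proboscis and glossa, family-specific for the
prementum).  Two auxiliary estimators ride along: dry body mass from IT by
inverting Cane's regression IT = c * mass^e, and foraging/homing distance
from published log-log distance-body-size regressions.

Predictions are species-level: within a species, individual IT is a weak
predictor of individual mouthpart length (intraspecific R^2 is typically
0.1-0.4), so these estimates should not be read as per-individual claims.
Some groups are known to break the family-level model — euglossine bees in
particular have far longer tongues than other Apidae of the same size —
and for such taxa direct measurement remains preferable.

Note the engine never sums part predictions: the predicted proboscis comes
from its own fitted coefficients and generally differs slightly from
predicted glossa + predicted prementum.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AllometricCoefficients,
    BodyMassConstants,
    ForagingDistanceConstants,
    PARTS,
    SpecimenRecord,
    UnknownFamilyError,
    load_body_mass_constants,
    load_coefficients,
    load_foraging_constants,
    load_it_ranges,
    validate_family,
)

__all__ = [
    "predict_part_length",
    "estimate_body_mass",
    "invert_body_mass",
    "estimate_foraging_distance",
    "predict_batch",
]


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value}")
    return value


def predict_part_length(
    it_mm: float,
    family: str,
    part: str,
    coeffs: AllometricCoefficients | Mapping[str, AllometricCoefficients] | None = None,
    *,
    it_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, bool]:
    """Predict the length (mm) of one mouthpart from IT and family.

    Returns ``(length_mm, extrapolated)`` where ``extrapolated`` is True
    when ``it_mm`` lies outside the configured observed IT range for the
    family (the fit is not constrained there).  ``coeffs`` defaults to the
    packaged interspecific OLS coefficient set.
    """
    it_mm = _check_positive(it_mm, "it_mm")
    family = validate_family(family)
    if part not in PARTS:
        raise ValueError(f"part must be one of {PARTS}, got {part!r}")
    if coeffs is None:
        coeffs = load_coefficients()
    if isinstance(coeffs, Mapping):
        try:
            coeffs = coeffs[part]
        except KeyError:
            raise KeyError(f"no coefficient set for part {part!r}") from None
    if coeffs.part != part:
        raise ValueError(f"coefficient set is for {coeffs.part!r}, not {part!r}")
    a, b = coeffs.ab(family)
    if it_ranges is None:
        it_ranges = load_it_ranges()
    lo, hi = it_ranges.get(family, (-math.inf, math.inf))
    extrapolated = not (lo <= it_mm <= hi)
    return a * it_mm**b, extrapolated


def estimate_body_mass(
    it_mm: float, k: BodyMassConstants | None = None
) -> float:
    """Dry body mass (mg) from IT (mm): mass = (IT / c)^(1/e)."""
    it_mm = _check_positive(it_mm, "it_mm")
    if k is None:
        k = load_body_mass_constants()
    return (it_mm / k.c) ** (1.0 / k.e)


def invert_body_mass(mass_mg: float, k: BodyMassConstants | None = None) -> float:
    """IT (mm) from dry body mass (mg): IT = c * mass^e.

    Exact inverse of :func:`estimate_body_mass`.
    """
    mass_mg = _check_positive(mass_mg, "mass_mg")
    if k is None:
        k = load_body_mass_constants()
    return k.c * mass_mg**k.e


def estimate_foraging_distance(
    it_mm: float,
    metric: str = "typical_homing",
    k: ForagingDistanceConstants | None = None,
) -> float:
    """Foraging/homing distance (km) from IT (mm) for one distance metric."""
    it_mm = _check_positive(it_mm, "it_mm")
    if k is None:
        k = load_foraging_constants()
    intercept, slope = k.line(metric)
    return 10.0 ** (intercept + slope * math.log10(it_mm))


def predict_batch(
    records: Sequence[SpecimenRecord] | pd.DataFrame,
    coeffs: Mapping[str, AllometricCoefficients] | None = None,
    *,
    parts: Sequence[str] = PARTS,
    mass: bool = True,
    foraging_metric: str | None = None,
    body_mass_constants: BodyMassConstants | None = None,
    foraging_constants: ForagingDistanceConstants | None = None,
    it_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Predict all requested quantities for a table of bees.

    Accepts either validated :class:`SpecimenRecord` objects or any
    DataFrame with ``species``/``family``/``it_mm`` columns (so unvalidated
    rows with unsupported families can be carried through).  One output row
    per input row; rows that cannot be predicted (unknown family,
    non-positive IT) get NaN predictions plus a ``reason`` column entry —
    never a silent drop.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy().reset_index(drop=True)
    else:
        from .io import specimens_to_frame

        df = specimens_to_frame(list(records))
    base_cols = ["species", "family", "it_mm"]
    pred_cols = [f"pred_{p}_mm" for p in parts]
    if mass:
        pred_cols.append("pred_mass_mg")
    if foraging_metric is not None:
        pred_cols.append(f"pred_{foraging_metric}_km")
    if df.empty:
        cols = [c for c in df.columns] or base_cols
        return pd.DataFrame(columns=cols + pred_cols + ["extrapolated", "reason"])

    missing = [c for c in base_cols if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing column(s): {missing}")

    if coeffs is None:
        coeffs = load_coefficients()
    if it_ranges is None:
        it_ranges = load_it_ranges()

    preds = {c: np.full(len(df), np.nan) for c in pred_cols}
    extrapolated = np.zeros(len(df), dtype=bool)
    reasons = [""] * len(df)
    for i, row in df.iterrows():
        try:
            family = validate_family(row["family"])
            it = _check_positive(row["it_mm"], "it_mm")
        except (UnknownFamilyError, ValueError, TypeError) as exc:
            reasons[i] = str(exc)
            continue
        for p in parts:
            y, ex = predict_part_length(it, family, p, coeffs, it_ranges=it_ranges)
            preds[f"pred_{p}_mm"][i] = y
            extrapolated[i] |= ex
        if mass:
            preds["pred_mass_mg"][i] = estimate_body_mass(it, body_mass_constants)
        if foraging_metric is not None:
            preds[f"pred_{foraging_metric}_km"][i] = estimate_foraging_distance(
                it, foraging_metric, foraging_constants
            )
    out = df.copy()
    for c in pred_cols:
        out[c] = preds[c]
    out["extrapolated"] = extrapolated
    out["reason"] = reasons
    return out
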