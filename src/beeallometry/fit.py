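"""Interspecific log-log OLS fitting and AIC model selection.

The response is the natural log of a species-mean mouthpart length and the
predictor the natural log of species-mean IT.  Candidate mean structures
combine a grouping factor (family, tongue type, or none) with the ln(IT)
slope, optionally interacted with the grouping, giving the seven admissible
models per response:

    Family + IT, Family x IT, TongueType + IT, TongueType x IT,
    IT only, Family only, TongueType only.

Fits are unweighted ordinary least squares across species (each species
mean counts once regardless of how many specimens produced it; a
``weights`` option is provided for sensitivity analyses).  AIC uses the
Gaussian maximum-likelihood convention that counts the error variance as a
parameter and keeps the additive constants:

    AIC = n * ln(2*pi*RSS/n) + n + 2*(k + 1)

with k the number of mean-structure parameters.  Because AIC conventions
differ between software packages only differences within one convention are
meaningful; this one matches standard linear-model AIC reporting.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    FAMILIES,
    AllometricCoefficients,
    SpeciesMeans,
    means_to_frame,
    tongue_type,
)

__all__ = [
    "ModelSpec",
    "OLSFit",
    "CANDIDATE_SPECS",
    "candidate_specs",
    "fit_ols",
    "aic_of",
    "model_selection",
    "extract_coefficients",
]

_RESPONSE_COL = {
    "proboscis": "mean_proboscis_mm",
    "glossa": "mean_glossa_mm",
    "prementum": "mean_prementum_mm",
}


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One candidate mean structure for ln(response) ~ ln(IT)."""

    response: str
    grouping: str = "none"  # family | tongue_type | none
    include_it: bool = True
    interaction: bool = False

    def __post_init__(self):
        if self.response not in _RESPONSE_COL:
            raise ValueError(f"response must be one of {tuple(_RESPONSE_COL)}")
        if self.grouping not in ("family", "tongue_type", "none"):
            raise ValueError("grouping must be family, tongue_type or none")
        if self.interaction and (not self.include_it or self.grouping == "none"):
            raise ValueError("interaction requires include_it and a grouping")
        if not self.include_it and self.grouping == "none":
            raise ValueError("model must include at least IT or a grouping")

    @property
    def label(self) -> str:
        g = {"family": "Family", "tongue_type": "TongueType"}.get(self.grouping)
        if g is None:
            return "IT only"
        if not self.include_it:
            return f"{g} only"
        return f"{g} {'x' if self.interaction else '+'} IT"


def candidate_specs(response: str) -> list[ModelSpec]:
    """The seven admissible models for one response."""
    out = []
    for grouping in ("family", "tongue_type"):
        out.append(ModelSpec(response, grouping, include_it=True, interaction=False))
        out.append(ModelSpec(response, grouping, include_it=True, interaction=True))
        out.append(ModelSpec(response, grouping, include_it=False))
    out.append(ModelSpec(response, "none", include_it=True))
    return out


CANDIDATE_SPECS: Mapping[str, tuple[ModelSpec, ...]] = {
    r: tuple(candidate_specs(r)) for r in _RESPONSE_COL
}


@dataclasses.dataclass(frozen=True)
class OLSFit:
    """A fitted candidate model (all coefficients on the ln scale)."""

    spec: ModelSpec
    coefficients: Mapping[str, float]
    n: int
    k: int
    rss: float
    tss: float
    aic: float
    slope_se: Mapping[str, float] | None = None

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss

    @property
    def sigma2_ml(self) -> float:
        return self.rss / self.n


def _design(df: pd.DataFrame, spec: ModelSpec):
    """Build the design matrix with a cell-means parametrisation.

    Groups get their own intercept column (no reference level), so the
    intercept coefficients are directly the per-group ln(a) values.
    """
    x = np.log(df["mean_it_mm"].to_numpy(dtype=float))
    n = len(df)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.grouping == "none":
        cols.append(np.ones(n))
        names.append("intercept")
        groups = None
    else:
        if spec.grouping == "family":
            g = df["family"].astype(str).to_numpy()
        else:
            g = np.array([tongue_type(f) for f in df["family"]])
        groups = sorted(set(g))
        for lvl in groups:
            cols.append((g == lvl).astype(float))
            names.append(f"intercept[{lvl}]")
    if spec.include_it:
        if spec.interaction:
            for lvl, ind in zip(groups, cols[: len(groups)]):
                cols.append(ind * x)
                names.append(f"ln_it[{lvl}]")
        else:
            cols.append(x)
            names.append("ln_it")
    X = np.column_stack(cols)
    return X, names, groups


def fit_ols(
    data: Sequence[SpeciesMeans] | pd.DataFrame,
    spec: ModelSpec,
    *,
    weights: np.ndarray | None = None,
) -> OLSFit:
    """Least-squares fit of ln(response) for one candidate model.

    Raises ``ValueError`` on a singular design, naming the deficient group
    (e.g. a family contributing a single species under an interaction
    model).
    """
    df = data if isinstance(data, pd.DataFrame) else means_to_frame(list(data))
    ycol = _RESPONSE_COL[spec.response]
    df = df.dropna(subset=["mean_it_mm", ycol]).reset_index(drop=True)
    n = len(df)
    X, names, groups = _design(df, spec)
    k = X.shape[1]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} species to fit {spec.label}, got {n}")
    y = np.log(df[ycol].to_numpy(dtype=float))
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    if np.linalg.matrix_rank(Xw) < k:
        # identify which group starves the design
        bad = []
        if groups is not None and spec.interaction:
            if spec.grouping == "family":
                counts = df["family"].value_counts()
            else:
                counts = df["family"].map(tongue_type).value_counts()
            bad = [g for g in groups if counts.get(g, 0) < 2]
        raise ValueError(
            "singular design for model "
            f"{spec.label}" + (f"; deficient group(s): {bad}" if bad else "")
        )
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((yw - yw.mean()) ** 2))
    coefficients = dict(zip(names, beta))

    # standard errors for the ln(IT) slope term(s), for CI reporting
    dof = n - k
    slope_se = None
    if spec.include_it and dof > 0:
        s2 = rss / dof
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        slope_se = {
            name: float(math.sqrt(s2 * XtX_inv[i, i]))
            for i, name in enumerate(names)
            if name.startswith("ln_it")
        }

    fit = OLSFit(
        spec=spec,
        coefficients=coefficients,
        n=n,
        k=k,
        rss=rss,
        tss=tss,
        aic=float("nan"),
        slope_se=slope_se,
    )
    return dataclasses.replace(fit, aic=aic_of(fit))


def aic_of(fit: OLSFit) -> float:
    """Gaussian ML AIC of a fit: n*ln(2*pi*RSS/n) + n + 2*(k+1).

    The error variance counts as a parameter.  A perfect fit (RSS = 0) has
    no finite ML AIC; ``-inf`` is returned with a warning so the model
    still ranks first.
    """
    if fit.rss <= 0:
        warnings.warn(
            "RSS = 0: Gaussian AIC is undefined; returning -inf", RuntimeWarning
        )
        return float("-inf")
    n, k = fit.n, fit.k
    return n * math.log(2 * math.pi * fit.rss / n) + n + 2 * (k + 1)


def model_selection(
    data: Sequence[SpeciesMeans] | pd.DataFrame,
    response: str,
    *,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit all seven candidate models and rank them by ascending AIC.

    Ties (ΔAIC below 1e-10) are broken toward fewer parameters.  Models
    that cannot be fitted (singular design) are reported with an ``error``
    column instead of aborting the whole ranking.  The returned frame has
    one row per candidate with columns model/r2/aic/k/n plus the fitted
    objects in ``fit``.
    """
    rows = []
    for spec in candidate_specs(response):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_ols(data, spec, weights=weights)
            rows.append(
                {
                    "model": spec.label,
                    "r2": fit.r2,
                    "aic": fit.aic,
                    "k": fit.k,
                    "n": fit.n,
                    "fit": fit,
                    "error": "",
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "model": spec.label,
                    "r2": np.nan,
                    "aic": np.inf,
                    "k": np.nan,
                    "n": np.nan,
                    "fit": None,
                    "error": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    out = out.sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    return out


def extract_coefficients(fit: OLSFit) -> AllometricCoefficients:
    """Convert a fitted family-grouped model into power-function coefficients.

    a_family = exp(family intercept); b is the shared ln(IT) slope, or the
    per-family slope map when the model included the family x IT
    interaction.  Only family-grouped models with IT qualify — tongue-type
    or intercept-only fits carry no family coefficients.
    """
    spec = fit.spec
    if spec.grouping != "family" or not spec.include_it:
        raise ValueError(
            "coefficients can only be extracted from a Family + IT or "
            f"Family x IT fit, not {spec.label!r}"
        )
    a = {}
    b_map = {}
    for name, value in fit.coefficients.items():
        if name.startswith("intercept["):
            a[name[len("intercept[") : -1]] = math.exp(value)
        elif name.startswith("ln_it["):
            b_map[name[len("ln_it[") : -1]] = value
    b = b_map if spec.interaction else fit.coefficients["ln_it"]
    return AllometricCoefficients(
        part=spec.response,
        a_by_family=a,
        b=b,
        provenance=f"fitted {spec.label}, n={fit.n}, R2={fit.r2:.4f}",
    )
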