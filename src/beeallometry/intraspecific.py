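"""Per-species (intraspecific) regressions of mouthpart length on IT.

For every species with at least ``min_n`` measured individuals, an OLS
regression of ln(length) on ln(IT) is fitted across individuals; when two
or more sex/caste levels occur in that species, sex/caste enters as an
additive factor.  The reported p-value is for the ln(IT) slope (the
scientific question is whether body size predicts mouthpart length within
a species, not whether the model as a whole explains anything), and the
reported r2 is the coefficient of determination of the fitted model.  No
multiple-testing correction is applied across species.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpecimenRecord, specimens_to_frame

__all__ = ["fit_intraspecific", "summarize_intraspecific"]

_RESPONSE_COL = {
    "proboscis": "proboscis_mm",
    "glossa": "glossa_mm",
    "prementum": "prementum_mm",
}


def _fit_one(grp: pd.DataFrame, ycol: str) -> dict | None:
    grp = grp.dropna(subset=["it_mm", ycol])
    n = len(grp)
    x = np.log(grp["it_mm"].to_numpy(dtype=float))
    y = np.log(grp[ycol].to_numpy(dtype=float))
    levels = sorted(grp["sex_caste"].astype(str).unique())
    sex_included = len(levels) >= 2
    cols = [np.ones(n), x]
    if sex_included:
        for lvl in levels[1:]:
            cols.append((grp["sex_caste"].astype(str) == lvl).to_numpy(dtype=float))
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k or np.linalg.matrix_rank(X) < k or np.var(x) == 0:
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    dof = n - k
    s2 = rss / dof if dof > 0 else float("nan")
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(s2 * XtX_inv[1, 1]) if dof > 0 else float("nan")
    slope = float(beta[1])
    if se > 0 and math.isfinite(se):
        t = slope / se
        p = 2.0 * stats.t.sf(abs(t), dof)
    else:
        p = 0.0 if rss == 0 else float("nan")
    return {
        "n": n,
        "slope": slope,
        "r2": r2,
        "p": float(p),
        "sex_included": sex_included,
    }


def fit_intraspecific(
    records: Sequence[SpecimenRecord] | pd.DataFrame,
    response: str = "proboscis",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-species OLS of ln(response) on ln(IT) (+ sex/caste if present).

    Species with fewer than ``min_n`` usable individuals are excluded.
    Returns a frame indexed by species with columns
    n / slope / r2 / p / sex_included; an empty frame when no species
    qualifies.
    """
    ycol = _RESPONSE_COL[response]
    df = records if isinstance(records, pd.DataFrame) else specimens_to_frame(list(records))
    out_cols = ["species", "n", "slope", "r2", "p", "sex_included"]
    if df.empty or ycol not in df.columns:
        return pd.DataFrame(columns=out_cols).set_index("species")
    rows = []
    for species, grp in df.dropna(subset=["it_mm", ycol]).groupby("species", sort=True):
        if len(grp) < min_n:
            continue
        res = _fit_one(grp, ycol)
        if res is None:
            continue
        rows.append({"species": species, **res})
    if not rows:
        return pd.DataFrame(columns=out_cols).set_index("species")
    return pd.DataFrame(rows).set_index("species")


def summarize_intraspecific(
    table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, float]:
    """Summarise a per-species table: how many species show a significant
    IT slope, and the mean r2 overall and among the significant ones."""
    if table.empty:
        raise ValueError("empty intraspecific table")
    sig = table["p"] < alpha
    return {
        "n_species": int(len(table)),
        "count_significant": int(sig.sum()),
        "mean_r2": float(table["r2"].mean()),
        "mean_r2_significant": float(table.loc[sig, "r2"].mean())
        if sig.any()
        else float("nan"),
    }
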