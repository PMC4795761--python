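"""Domain types, validation and tabular I/O for bee morphometric data.

The package works with two tabular layers:

* specimen tables — one row per measured bee (species, family, sex/caste,
  intertegular distance ``it_mm`` and the mouthpart lengths in mm), and
* species-means tables — one row per species with arithmetic means of the
  same measurements, which is the level at which the interspecific
  allometric models are fitted.

All lengths are millimetres.  Families are restricted to the five
well-sampled bee families (Andrenidae, Apidae, Colletidae, Halictidae,
Megachilidae); Melittidae and Stenotritidae are deliberately rejected
because no coefficients exist for them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# ---------------------------------------------------------------------------
# Families and the long-/short-tongued dichotomy
# ---------------------------------------------------------------------------

#: The five supported bee families.
FAMILIES: tuple[str, ...] = (
    "Andrenidae",
    "Apidae",
    "Colletidae",
    "Halictidae",
    "Megachilidae",
)

#: Apidae + Megachilidae form the monophyletic long-tongued clade; the
#: remaining three families are the classical short-tongued assemblage.
LONG_TONGUED: frozenset[str] = frozenset({"Apidae", "Megachilidae"})

PARTS: tuple[str, ...] = ("proboscis", "glossa", "prementum")

SEX_CASTES: tuple[str, ...] = ("female", "male", "queen", "worker", "unknown")


class UnknownFamilyError(ValueError):
    """Raised when a family outside the five supported ones is supplied."""

    def __init__(self, family: str):
        super().__init__(
            f"Unknown bee family {family!r}; supported families are "
            f"{', '.join(FAMILIES)}. (No coefficients exist for other "
            "families such as Melittidae or Stenotritidae.)"
        )
        self.family = family


def validate_family(family: str) -> str:
    """Return the canonical family name, or raise :class:`UnknownFamilyError`.

    Matching is case-insensitive but never fuzzy: unknown names are
    rejected, not coerced.
    """
    canon = str(family).strip().capitalize()
    if canon not in FAMILIES:
        raise UnknownFamilyError(family)
    return canon


def tongue_type(family: str) -> str:
    """Map a family to ``"long"`` or ``"short"`` tongue type."""
    return "long" if validate_family(family) in LONG_TONGUED else "short"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

#: Relative tolerance for the additivity check
#: proboscis = glossa + prementum.
PROBOSCIS_SUM_RTOL = 0.01


@dataclasses.dataclass(frozen=True)
class SpecimenRecord:
    """One measured bee.

    ``proboscis_mm``, when present alongside both parts, must equal
    ``glossa_mm + prementum_mm`` within 1% (the proboscis is defined as
    glossa plus prementum).
    """

    species: str
    family: str
    it_mm: float
    sex_caste: str = "unknown"
    genus: str | None = None
    glossa_mm: float | None = None
    prementum_mm: float | None = None
    proboscis_mm: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "family", validate_family(self.family))
        if not self.species or not str(self.species).strip():
            raise ValueError("species name must be non-empty")
        if self.sex_caste not in SEX_CASTES:
            raise ValueError(
                f"sex_caste {self.sex_caste!r} not one of {SEX_CASTES}"
            )
        for name in ("it_mm", "glossa_mm", "prementum_mm", "proboscis_mm"):
            v = getattr(self, name)
            if v is None:
                if name == "it_mm":
                    raise ValueError("it_mm is mandatory")
                continue
            v = float(v)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite length, got {v}")
            object.__setattr__(self, name, v)
        if (
            self.glossa_mm is not None
            and self.prementum_mm is not None
            and self.proboscis_mm is not None
        ):
            total = self.glossa_mm + self.prementum_mm
            if abs(self.proboscis_mm - total) > PROBOSCIS_SUM_RTOL * total:
                raise ValueError(
                    f"proboscis_mm={self.proboscis_mm} is not glossa+prementum"
                    f"={total:.4g} within {PROBOSCIS_SUM_RTOL:.0%}"
                )

    @property
    def tongue_type(self) -> str:
        return tongue_type(self.family)


@dataclasses.dataclass(frozen=True)
class SpeciesMeans:
    """Species-level arithmetic means of IT and mouthpart lengths (mm)."""

    species: str
    family: str
    n_specimens: int
    mean_it_mm: float
    mean_glossa_mm: float | None = None
    mean_prementum_mm: float | None = None
    mean_proboscis_mm: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "family", validate_family(self.family))
        if int(self.n_specimens) < 1:
            raise ValueError("n_specimens must be >= 1")
        object.__setattr__(self, "n_specimens", int(self.n_specimens))
        for name in (
            "mean_it_mm",
            "mean_glossa_mm",
            "mean_prementum_mm",
            "mean_proboscis_mm",
        ):
            v = getattr(self, name)
            if v is None:
                if name == "mean_it_mm":
                    raise ValueError("mean_it_mm is mandatory")
                continue
            v = float(v)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            object.__setattr__(self, name, v)

    @property
    def tongue_type(self) -> str:
        return tongue_type(self.family)


# ---------------------------------------------------------------------------
# Coefficients and auxiliary constants
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AllometricCoefficients:
    """Coefficients of the power function Y = a_family * IT^b for one part.

    ``b`` is a single shared scaling exponent when the fitted model had no
    family x IT interaction, and a per-family map when it did.
    """

    part: str
    a_by_family: Mapping[str, float]
    b: float | Mapping[str, float]
    provenance: str = ""

    def __post_init__(self):
        if self.part not in PARTS:
            raise ValueError(f"part must be one of {PARTS}, got {self.part!r}")
        a = {validate_family(f): float(v) for f, v in self.a_by_family.items()}
        if any(v <= 0 for v in a.values()):
            raise ValueError("all a coefficients must be positive")
        object.__setattr__(self, "a_by_family", a)
        if isinstance(self.b, Mapping):
            b = {validate_family(f): float(v) for f, v in self.b.items()}
            if set(b) != set(a):
                raise ValueError(
                    "per-family b must cover exactly the families in a_by_family"
                )
            object.__setattr__(self, "b", b)
        else:
            object.__setattr__(self, "b", float(self.b))

    @property
    def per_family_b(self) -> bool:
        return isinstance(self.b, Mapping)

    def families(self) -> tuple[str, ...]:
        return tuple(sorted(self.a_by_family))

    def ab(self, family: str) -> tuple[float, float]:
        """Return (a, b) for one family."""
        fam = validate_family(family)
        if fam not in self.a_by_family:
            raise KeyError(f"no {self.part} coefficients for family {fam}")
        b = self.b[fam] if self.per_family_b else self.b
        return self.a_by_family[fam], b


@dataclasses.dataclass(frozen=True)
class BodyMassConstants:
    """Constants of the IT–dry-mass relationship IT = c * mass^e.

    Defaults are Cane's regression for bees (IT in mm, dry mass in mg):
    c = 0.77, e = 0.405.
    """

    c: float = 0.77
    e: float = 0.405
    provenance: str = "Cane 1987, J. Kansas Entomol. Soc. 60:145-147"

    def __post_init__(self):
        if self.c <= 0 or self.e <= 0:
            raise ValueError("c and e must be positive")


@dataclasses.dataclass(frozen=True)
class ForagingDistanceConstants:
    """Log-log regressions of foraging/homing distance (km) on IT (mm).

    Each metric maps to ``(intercept, slope)`` of
    ``log10(distance km) = intercept + slope * log10(IT mm)``.
    """

    lines: Mapping[str, tuple[float, float]]
    provenance: str = ""

    def metrics(self) -> tuple[str, ...]:
        return tuple(sorted(self.lines))

    def line(self, metric: str) -> tuple[float, float]:
        try:
            intercept, slope = self.lines[metric]
        except KeyError:
            raise KeyError(
                f"unknown foraging metric {metric!r}; available: "
                f"{', '.join(self.metrics())}"
            ) from None
        return float(intercept), float(slope)


_DATA_DIR = Path(__file__).parent / "data"


def load_coefficients(path: str | Path | None = None, part: str | None = None):
    """Load allometric coefficients from a JSON file.

    With no ``path`` the packaged interspecific OLS coefficient set is
    used.  Returns a dict part -> :class:`AllometricCoefficients`, or a
    single instance if ``part`` is given.
    """
    p = Path(path) if path is not None else _DATA_DIR / "coefficients.json"
    payload = json.loads(p.read_text())
    provenance = payload.get("provenance", "")
    out = {}
    for entry in payload["parts"]:
        out[entry["part"]] = AllometricCoefficients(
            part=entry["part"],
            a_by_family=entry["a"],
            b=entry["b"],
            provenance=entry.get("provenance", provenance),
        )
    if part is not None:
        return out[part]
    return out


def save_coefficients(
    coeffs: Mapping[str, AllometricCoefficients] | AllometricCoefficients,
    path: str | Path,
    provenance: str = "",
) -> None:
    """Write coefficients to JSON in the same format ``load_coefficients`` reads."""
    if isinstance(coeffs, AllometricCoefficients):
        coeffs = {coeffs.part: coeffs}
    payload = {
        "provenance": provenance,
        "parts": [
            {
                "part": c.part,
                "a": dict(c.a_by_family),
                "b": dict(c.b) if c.per_family_b else c.b,
                "provenance": c.provenance,
            }
            for c in coeffs.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_body_mass_constants(path: str | Path | None = None) -> BodyMassConstants:
    p = Path(path) if path is not None else _DATA_DIR / "body_mass.json"
    d = json.loads(p.read_text())
    return BodyMassConstants(c=d["c"], e=d["e"], provenance=d.get("provenance", ""))


def load_foraging_constants(
    path: str | Path | None = None,
) -> ForagingDistanceConstants:
    p = Path(path) if path is not None else _DATA_DIR / "foraging_distance.json"
    d = json.loads(p.read_text())
    lines = {k: (v["intercept"], v["slope"]) for k, v in d["metrics"].items()}
    return ForagingDistanceConstants(lines=lines, provenance=d.get("provenance", ""))


def load_it_ranges(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Per-family (min, max) IT in mm used for the extrapolation flag."""
    p = Path(path) if path is not None else _DATA_DIR / "it_ranges.json"
    d = json.loads(p.read_text())
    return {validate_family(f): (float(lo), float(hi)) for f, (lo, hi) in d["ranges"].items()}


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

# Header aliases accepted on input (case-insensitive), so a species table
# exported from a spreadsheet with plain column names loads unchanged.
_SPECIMEN_ALIASES = {
    "species": "species",
    "family": "family",
    "genus": "genus",
    "sex": "sex_caste",
    "caste": "sex_caste",
    "sex_caste": "sex_caste",
    "it": "it_mm",
    "it_mm": "it_mm",
    "intertegular_distance": "it_mm",
    "glossa": "glossa_mm",
    "glossa_mm": "glossa_mm",
    "prementum": "prementum_mm",
    "prementum_mm": "prementum_mm",
    "proboscis": "proboscis_mm",
    "proboscis_mm": "proboscis_mm",
}

_MEANS_ALIASES = {
    "species": "species",
    "family": "family",
    "n": "n_specimens",
    "n_specimens": "n_specimens",
    "it": "mean_it_mm",
    "it_mm": "mean_it_mm",
    "mean_it_mm": "mean_it_mm",
    "glossa": "mean_glossa_mm",
    "glossa_mm": "mean_glossa_mm",
    "mean_glossa_mm": "mean_glossa_mm",
    "prementum": "mean_prementum_mm",
    "prementum_mm": "mean_prementum_mm",
    "mean_prementum_mm": "mean_prementum_mm",
    "proboscis": "mean_proboscis_mm",
    "proboscis_mm": "mean_proboscis_mm",
    "mean_proboscis_mm": "mean_proboscis_mm",
}


class RowError(ValueError):
    """A row-level validation failure with a 1-based data line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"row {line}: {message}")
        self.line = line
        self.row_message = message


def _normalise_header(columns: Iterable[str], aliases: Mapping[str, str]) -> dict[str, str]:
    out = {}
    for col in columns:
        key = str(col).strip().lower().replace(" ", "_")
        if key in aliases:
            out[col] = aliases[key]
    return out


def _read_table(path: str | Path, aliases, mandatory: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    rename = _normalise_header(df.columns, aliases)
    df = df.rename(columns=rename)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"recognised headers: {sorted(set(aliases))}"
        )
    return df


def read_specimens(
    path: str | Path, *, strict: bool = False
) -> tuple[list[SpecimenRecord], list[RowError]]:
    """Read a specimen CSV (or spreadsheet) into validated records.

    Returns ``(records, errors)``: rows that fail validation (unknown
    family, non-positive lengths, proboscis != glossa + prementum) are
    collected as :class:`RowError` with their data line number.  With
    ``strict=True`` the first bad row raises instead.
    """
    df = _read_table(path, _SPECIMEN_ALIASES, ["species", "family", "it_mm"])
    records: list[SpecimenRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        kwargs = {}
        for field in (
            "species",
            "family",
            "genus",
            "sex_caste",
            "it_mm",
            "glossa_mm",
            "prementum_mm",
            "proboscis_mm",
        ):
            v = d.get(field)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            kwargs[field] = v
        if "sex_caste" in kwargs:
            kwargs["sex_caste"] = str(kwargs["sex_caste"]).strip().lower()
        try:
            records.append(SpecimenRecord(**kwargs))
        except ValueError as exc:
            err = RowError(i, str(exc))
            if strict:
                raise err from exc
            errors.append(err)
    return records, errors


def read_species_means(path: str | Path) -> list[SpeciesMeans]:
    """Read a species-means table (CSV, or the supplementary spreadsheet
    exported with its original headers)."""
    df = _read_table(path, _MEANS_ALIASES, ["species", "family", "mean_it_mm"])
    if "n_specimens" not in df.columns:
        df["n_specimens"] = 1
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        kwargs = {
            k: d[k]
            for k in (
                "species",
                "family",
                "n_specimens",
                "mean_it_mm",
                "mean_glossa_mm",
                "mean_prementum_mm",
                "mean_proboscis_mm",
            )
            if k in d
            and d[k] is not None
            and not (isinstance(d[k], float) and math.isnan(d[k]))
        }
        try:
            out.append(SpeciesMeans(**kwargs))
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
    dupes = pd.Series([m.species for m in out])
    if dupes.duplicated().any():
        raise ValueError(
            f"duplicate species rows: {sorted(dupes[dupes.duplicated()])}"
        )
    return out


def specimens_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def means_to_frame(means: Sequence[SpeciesMeans]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in means])


def write_species_means(means: Sequence[SpeciesMeans], path: str | Path) -> None:
    means_to_frame(means).to_csv(path, index=False)


def write_specimens(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    specimens_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def species_means(
    records: Sequence[SpecimenRecord], *, log_scale: bool = False
) -> list[SpeciesMeans]:
    """Collapse specimens to one row of per-species means.

    Means are arithmetic on the raw mm scale by default (the scale on which
    the interspecific points are defined); ``log_scale=True`` averages on
    the ln scale instead (geometric means), offered for sensitivity
    analyses.  Mixed families under one species name are an error.
    """
    if not records:
        return []
    df = specimens_to_frame(records)
    fam_counts = df.groupby("species")["family"].nunique()
    mixed = fam_counts[fam_counts > 1]
    if len(mixed):
        raise ValueError(
            f"species assigned to more than one family: {sorted(mixed.index)}"
        )

    import numpy as np

    def _mean(s: pd.Series) -> float | None:
        s = s.dropna()
        if s.empty:
            return None
        if log_scale:
            return float(np.exp(np.log(s.astype(float)).mean()))
        return float(s.mean())

    out = []
    for species, grp in df.groupby("species", sort=True):
        out.append(
            SpeciesMeans(
                species=str(species),
                family=grp["family"].iloc[0],
                n_specimens=len(grp),
                mean_it_mm=_mean(grp["it_mm"]),
                mean_glossa_mm=_mean(grp["glossa_mm"]),
                mean_prementum_mm=_mean(grp["prementum_mm"]),
                mean_proboscis_mm=_mean(grp["proboscis_mm"]),
            )
        )
    return out
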