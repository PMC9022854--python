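"""Long-format burden measure tables and direct age standardization.

The canonical in-memory container is a pandas DataFrame in the long layout
used by GBD Results Tool extracts: one row per (location, year, sex,
age_group, measure) carrying a rate per 100,000 (prevalence per 100,000
persons).  Six measures are recognised: incidence, deaths, prevalence,
yll, yld, daly.  An optional ``sdi`` column (socio-demographic index in
[0, 1]) is validated and carried through when present.

Age standardization is the direct method: a weighted sum of age-specific
rates under a reference age structure whose weights sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DuplicateKeyError,
    SchemaError,
    ValidationError,
)

#: Schema columns every measure table must carry, in canonical order.
SCHEMA_COLUMNS = ["location", "year", "sex", "age_group", "measure", "value"]

#: The six primary burden measures the index is built from.
MEASURES = ["incidence", "deaths", "prevalence", "yll", "yld", "daly"]

SEXES = ["female", "male", "both"]

#: Reserved age-group labels for aggregate rows.
AGE_STANDARDIZED = "age-standardized"
ALL_AGES = "all-ages"

#: Columns identifying a unique record.
KEY_COLUMNS = ["location", "year", "sex", "age_group", "measure"]


def default_age_bins(top: int = 95, width: int = 5) -> list[str]:
    """GBD-style age bin labels: ``0-4`` ... ``90-94``, open-ended ``95+``."""
    bins = [f"{lo}-{lo + width - 1}" for lo in range(0, top, width)]
    bins.append(f"{top}+")
    return bins


def age_bin_midpoint(label: str, open_width: float = 5.0) -> float:
    """Midpoint in years of a 5-year bin label; ``95+`` maps to 95 + width/2."""
    if label.endswith("+"):
        lo = float(label[:-1])
        return lo + open_width / 2.0
    lo, hi = label.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0


@dataclass(frozen=True)
class AgeStandard:
    """A reference age structure for direct standardization.

    Parameters
    ----------
    weights
        Mapping of age-group label to a weight in [0, 1].  Weights must sum
        to 1 within 1e-9.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = np.asarray(list(self.weights.values()), dtype=float)
        if len(w) == 0:
            raise ValidationError("age standard has no age groups")
        if np.any(~np.isfinite(w)) or np.any(w < 0) or np.any(w > 1):
            raise ValidationError("age-standard weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"age-standard weights sum to {w.sum():.12g}, expected 1"
            )

    @classmethod
    def equal(cls, age_groups: Iterable[str] | None = None) -> "AgeStandard":
        """Equal weight on every configured bin (default reference)."""
        groups = list(age_groups) if age_groups is not None else default_age_bins()
        n = len(groups)
        # distribute the rounding residue onto the last bin so the sum is exact
        w = {g: 1.0 / n for g in groups}
        w[groups[-1]] = 1.0 - (n - 1) / n
        return cls(w)

    @property
    def age_groups(self) -> list[str]:
        return list(self.weights.keys())


def age_standardize(rates: Mapping[str, float] | pd.Series, standard: AgeStandard) -> float:
    """Directly age-standardize an age-specific rate series.

    Returns ``sum_a weight_a * rate_a`` over the standard's age groups; the
    result keeps the input units (per 100,000).  Every age group in the
    standard must be present in ``rates``.
    """
    if isinstance(rates, pd.Series):
        rates = rates.to_dict()
    missing = [g for g in standard.age_groups if g not in rates]
    if missing:
        raise CoverageError(f"rates missing age groups required by standard: {missing}")
    return float(sum(standard.weights[g] * float(rates[g]) for g in standard.age_groups))


def _require_columns(df: pd.DataFrame, where: str) -> None:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing required column(s) {missing}")


def validate_measure_table(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a long-format measure table and return a clean copy.

    Checks the six schema columns, non-negative finite values, known sex and
    measure labels, and — in strict mode — uniqueness of the record key.
    Unknown extra columns are dropped except ``sdi``, which is validated to
    [0, 1] and retained.
    """
    _require_columns(df, "measure table")
    keep = SCHEMA_COLUMNS + (["sdi"] if "sdi" in df.columns else [])
    out = df[keep].copy()
    out["year"] = out["year"].astype(int)
    out["value"] = out["value"].astype(float)

    bad = ~np.isfinite(out["value"].to_numpy()) | (out["value"].to_numpy() < 0)
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise ValidationError(
            f"row {idx}: value must be a finite non-negative rate, got "
            f"{out['value'].iloc[idx]!r}"
        )
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"unknown sex label(s): {sorted(out.loc[bad_sex, 'sex'].unique())}"
        )
    bad_measure = ~out["measure"].isin(MEASURES)
    if bad_measure.any():
        raise ValidationError(
            f"unknown measure label(s): {sorted(out.loc[bad_measure, 'measure'].unique())}"
        )
    if "sdi" in out.columns:
        sdi = out["sdi"].astype(float)
        ok = sdi.isna() | ((sdi >= 0) & (sdi <= 1))
        if not ok.all():
            raise ValidationError("sdi values must lie in [0, 1]")
        out["sdi"] = sdi
    if strict:
        dup = out.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            key = out.loc[dup.idxmax(), KEY_COLUMNS].to_dict()
            raise DuplicateKeyError(f"duplicate record key {key}")
    return out.reset_index(drop=True)


def read_measure_table(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a measure-table CSV (comma-separated, UTF-8 header).

    Row order is preserved.  In strict mode duplicated record keys are
    rejected; with ``strict=False`` they are kept verbatim.
    """
    df = pd.read_csv(path)
    return validate_measure_table(df, strict=strict)


def write_measure_table(table: pd.DataFrame, path) -> None:
    """Write a validated measure table so that reading it back reproduces the
    table field-for-field."""
    _require_columns(table, "measure table")
    cols = SCHEMA_COLUMNS + (["sdi"] if "sdi" in table.columns else [])
    table[cols].to_csv(path, index=False)
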