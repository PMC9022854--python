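"""Gender disparity ratio, SDI quintiles, and stratified summaries.

The gender disparity ratio (GDR) is the female index score divided by the
male score for the same location/year/age stratum.  Values above one mean
better measured care quality for females, below one for males, and one means
parity.  The division always uses pre-rounding scores — dividing scores
already rounded for reporting would inject spurious disparity — and the
ratio itself is rounded only when written out.

SDI (socio-demographic index) quintile assignment supports two modes:
``rank`` computes the 20/40/60/80th percentile boundaries over locations in
a reference year, while ``fixed_cutpoints`` applies user-supplied boundaries
(to replicate published cut-offs).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError

QUINTILE_LABELS = ["low", "low-middle", "middle", "high-middle", "high"]

GDR_KEY = ["location", "year", "age_group"]


def compute_gdr(qci: pd.DataFrame, qci_col: str = "qci") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Female-to-male ratio of index scores per sexless stratum.

    Returns ``(gdr, skipped)``.  ``gdr`` has one row per (location, year,
    age_group) where both sex-specific scores exist, are non-negative, and
    the male score is strictly positive.  ``skipped`` logs strata dropped
    for a missing sex (``missing_sex``), a zero male score
    (``zero_male_qci``), or a score below the fitting frame
    (``negative_qci``) — the ratio is undefined there, not zero, infinite
    or negative.
    """
    key = [c for c in GDR_KEY if c in qci.columns]
    sexed = qci[qci["sex"].isin(["female", "male"])]
    wide = sexed.pivot_table(index=key, columns="sex", values=qci_col, aggfunc="first")
    wide = wide.reindex(columns=["female", "male"])

    missing = wide["female"].isna() | wide["male"].isna()
    negative = ~missing & ((wide["female"] < 0) | (wide["male"] < 0))
    zero_male = ~missing & ~negative & (wide["male"] == 0)
    bad = missing | negative | zero_male
    skipped = wide.index.to_frame(index=False)[bad.to_numpy()].copy()
    skipped["reason"] = np.select(
        [missing[bad].to_numpy(), negative[bad].to_numpy()],
        ["missing_sex", "negative_qci"],
        default="zero_male_qci",
    )

    ok = wide[~bad]
    out = ok.index.to_frame(index=False)
    out["gdr"] = (ok["female"] / ok["male"]).to_numpy()
    return out.reset_index(drop=True), skipped.reset_index(drop=True)


def assign_sdi_quintiles(
    sdi: pd.DataFrame,
    method: str = "rank",
    cutpoints: Sequence[float] | None = None,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Label each location-year with an SDI quintile.

    Parameters
    ----------
    sdi
        Columns ``location``, ``year``, ``sdi`` (values in [0, 1]).
    method
        ``"rank"``: boundaries are the 20/40/60/80th percentiles of SDI over
        locations in ``reference_year`` (default: the latest year present),
        so every location keeps one quintile across years.
        ``"fixed_cutpoints"``: apply the four supplied boundaries directly.
    cutpoints
        Four strictly increasing values in [0, 1]; required in fixed mode.

    Ties on a boundary are broken by stable location-name order so the
    assignment is invariant to input row order.
    """
    df = sdi[["location", "year", "sdi"]].copy()
    if ((df["sdi"] < 0) | (df["sdi"] > 1)).any():
        raise ConfigError("sdi values must lie in [0, 1]")
    if method == "fixed_cutpoints":
        if cutpoints is None or len(cutpoints) != 4:
            raise ConfigError("fixed_cutpoints mode needs exactly 4 cutpoints")
        cp = np.asarray(cutpoints, dtype=float)
        if np.any(np.diff(cp) <= 0):
            raise ConfigError("cutpoints must be strictly increasing")
        df["quintile"] = pd.cut(
            df["sdi"],
            bins=[-np.inf, *cp, np.inf],
            labels=QUINTILE_LABELS,
            right=True,
        ).astype(str)
        return df
    if method != "rank":
        raise ConfigError(f"unknown quintile method {method!r}")

    year = int(reference_year if reference_year is not None else df["year"].max())
    ref = df[df["year"] == year].sort_values("location", kind="stable")
    ref = ref.drop_duplicates("location")
    n_loc = len(ref)
    if n_loc < 5:
        raise InsufficientDataError(
            f"rank quintiles need >= 5 locations in reference year {year}, got {n_loc}"
        )
    if ref["sdi"].nunique() < n_loc:
        warnings.warn(
            "tied SDI values; quintile assignment breaks ties by location order",
            stacklevel=2,
        )
    # rank over the reference year, ties broken by the stable location sort
    order = ref["sdi"].to_numpy().argsort(kind="stable")
    ranks = np.empty(n_loc, dtype=int)
    ranks[order] = np.arange(n_loc)
    quint = np.minimum(ranks * 5 // n_loc, 4)
    mapping = dict(zip(ref["location"], (QUINTILE_LABELS[q] for q in quint)))
    missing = set(df["location"]) - set(mapping)
    if missing:
        raise InsufficientDataError(
            f"locations absent from reference year {year}: {sorted(missing)[:5]}"
        )
    df["quintile"] = df["location"].map(mapping)
    return df


def summarize_by(
    table: pd.DataFrame,
    grouping: Sequence[str],
    value_col: str,
    aggregator: str = "mean",
    weight_col: str | None = None,
) -> pd.DataFrame:
    """Aggregate a score table by grouping keys.

    ``aggregator`` is ``mean`` or ``population_weighted_mean`` (needs
    ``weight_col``).  Rows with a missing value are skipped and counted in
    ``n_skipped``; ``n`` is the number of rows aggregated per group.
    """
    grouping = list(grouping)
    unknown = [g for g in grouping if g not in table.columns]
    if unknown:
        raise ConfigError(f"unknown grouping key(s): {unknown}")
    if aggregator not in ("mean", "population_weighted_mean"):
        raise ConfigError(f"unknown aggregator {aggregator!r}")
    if aggregator == "population_weighted_mean":
        if weight_col is None or weight_col not in table.columns:
            raise ConfigError("population_weighted_mean needs a weight column")

    df = table.copy()

    def _agg(grp: pd.DataFrame) -> pd.Series:
        ok = grp[grp[value_col].notna()]
        if aggregator == "mean":
            val = ok[value_col].mean()
        else:
            w = ok[weight_col].to_numpy(dtype=float)
            x = ok[value_col].to_numpy(dtype=float)
            val = float(np.sum(w * x) / np.sum(w)) if w.sum() > 0 else np.nan
        return pd.Series(
            {value_col: val, "n": len(ok), "n_skipped": len(grp) - len(ok)}
        )

    out = df.groupby(grouping, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n"] = out["n"].astype(int)
    out["n_skipped"] = out["n_skipped"].astype(int)
    return out
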