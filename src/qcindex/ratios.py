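"""Secondary burden ratios: the four inputs to the quality-of-care index.

From the six primary measures, each stratum yields four scale-free ratios:

``mir``
    mortality-to-incidence ratio (deaths rate / incidence rate).  With a
    stable incidence, higher mortality signals worse care.
``prev_inc``
    prevalence-to-incidence ratio.  With similar incidence, higher
    prevalence reflects better management that keeps patients alive.
``daly_prev``
    DALY-to-prevalence ratio.  At equal prevalence, higher total burden per
    prevalent case signals worse care.
``yll_yld``
    YLL-to-YLD ratio.  Measures the health system's ability to postpone
    death; higher values are worse.

Strata with a zero denominator (incidence, prevalence, or YLD) or with any
of the six measures absent are excluded — never silently — and the reason is
logged per stratum, mirroring the manual zero-estimate inspection that
precedes index construction on real extracts.  An epsilon-imputation mode is
available behind ``zero_policy="epsilon"`` but is off by default: imputing
tiny denominators distorts the PCA loadings downstream.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ConfigError
from .tables import AGE_STANDARDIZED, MEASURES

RATIO_COLUMNS = ["mir", "prev_inc", "daly_prev", "yll_yld"]

#: Direction of each ratio with respect to quality of care:
#: +1 means higher is worse, -1 means higher is better.
RATIO_DIRECTION = {"mir": +1, "prev_inc": -1, "daly_prev": +1, "yll_yld": +1}

EXCLUSION_REASONS = ["zero_incidence", "zero_prevalence", "zero_yld", "missing_measure"]

DEFAULT_FRAME: tuple[str, ...] = ("location", "year", "sex")


def compute_ratios(
    table: pd.DataFrame,
    frame: Sequence[str] = DEFAULT_FRAME,
    age_group: str | None = AGE_STANDARDIZED,
    zero_policy: str = "exclude",
    epsilon: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the four secondary ratios per stratum.

    Parameters
    ----------
    table
        Validated long-format measure table.
    frame
        Grouping keys defining one stratum (default location x year x sex).
        ``age_group`` is always part of the output key.
    age_group
        Restrict to this age-group label before grouping (default the
        age-standardized rows); ``None`` keeps all age groups and adds
        ``age_group`` to the stratum key.
    zero_policy
        ``"exclude"`` (default) drops strata whose incidence, prevalence or
        YLD rate is zero, logging the reason; ``"epsilon"`` replaces zero
        denominators by ``epsilon`` instead.

    Returns
    -------
    (ratios, exclusions)
        ``ratios`` has one row per retained stratum with the four ratio
        columns (plus ``sdi`` when present in the input); ``exclusions`` has
        the stratum key plus a ``reason`` column, one row per dropped
        stratum.

    Raises
    ------
    InsufficientDataError
        If no stratum survives — there is nothing to build an index from.
    """
    if zero_policy not in ("exclude", "epsilon"):
        raise ConfigError(f"unknown zero_policy {zero_policy!r}")
    frame = list(frame)
    df = table
    if age_group is not None:
        df = df[df["age_group"] == age_group]
    key = frame + (["age_group"] if "age_group" not in frame else [])

    wide = df.pivot_table(index=key, columns="measure", values="value", aggfunc="first")
    wide = wide.reindex(columns=MEASURES)
    if "sdi" in table.columns:
        sdi = df.groupby(key)["sdi"].first()
        wide = wide.join(sdi)

    reasons = pd.Series("", index=wide.index, dtype=object)
    missing = wide[MEASURES].isna().any(axis=1)
    reasons[missing] = "missing_measure"
    # denominator checks only where all six measures are present
    complete = ~missing
    if zero_policy == "exclude":
        reasons[complete & (wide["incidence"] == 0)] = "zero_incidence"
        reasons[complete & (wide["incidence"] > 0) & (wide["prevalence"] == 0)] = "zero_prevalence"
        reasons[
            complete
            & (wide["incidence"] > 0)
            & (wide["prevalence"] > 0)
            & (wide["yld"] == 0)
        ] = "zero_yld"
    else:
        for col in ("incidence", "prevalence", "yld"):
            wide.loc[complete & (wide[col] == 0), col] = epsilon

    excluded = reasons != ""
    exclusions = wide.index.to_frame(index=False)[excluded.to_numpy()].copy()
    exclusions["reason"] = reasons[excluded].to_numpy()

    kept = wide[~excluded]
    if kept.empty:
        raise InsufficientDataError(
            "no stratum has all six measures with positive denominators"
        )
    out = kept.index.to_frame(index=False)
    out["mir"] = (kept["deaths"] / kept["incidence"]).to_numpy()
    out["prev_inc"] = (kept["prevalence"] / kept["incidence"]).to_numpy()
    out["daly_prev"] = (kept["daly"] / kept["prevalence"]).to_numpy()
    out["yll_yld"] = (kept["yll"] / kept["yld"]).to_numpy()
    if "sdi" in kept.columns:
        out["sdi"] = kept["sdi"].to_numpy()
    return out.reset_index(drop=True), exclusions.reset_index(drop=True)


def summarize_exclusions(log: pd.DataFrame) -> dict[str, int]:
    """Tally an exclusion log by reason; reasons absent from the log get 0."""
    counts = Counter(log["reason"]) if len(log) else Counter()
    return {r: int(counts.get(r, 0)) for r in EXCLUSION_REASONS}
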