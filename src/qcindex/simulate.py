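"""Synthetic GBD-shaped burden data with known ground truth.

The generator produces long-format measure tables with the statistical
structure the index pipeline expects, driven by a single latent per-location
quality-of-care variable ``q`` in (0, 1):

* higher ``q`` lowers the mortality-to-incidence ratio (linear link from
  ``mir_ceil`` at q=0 down to ``mir_floor`` at q=1),
* higher ``q`` raises prevalent duration, hence the prevalence-to-incidence
  ratio (patients survive longer under better care),
* higher ``q`` lowers DALY-to-prevalence and YLL-to-YLD (fewer deaths means
  less life lost per prevalent case).

Age-specific incidence follows a logistic-in-age curve (rare in the young,
plateauing in old age, as for colorectal cancer); deaths, prevalence, YLD
and YLL are derived from it through the links above; DALY = YLL + YLD holds
exactly by construction, as in GBD itself.  Multiplicative log-normal noise
is applied per measure — rates are positive and burden-estimate errors are
heavier on the multiplicative scale.  Noise is drawn per (location, year,
age bin, measure) and shared across the sexes by default, so with
``sex_effect = 1`` the two sexes are exactly equal and the gender disparity
ratio is 1 by construction; set ``independent_sex_noise=True`` to add
sex-specific sampling noise.  The per-location SDI is a monotone link of
``q`` plus truncated Gaussian noise.

The generator targets structure, not the burden magnitudes of any real
cancer; its purpose is end-to-end pipeline testing against recoverable
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InsufficientDataError
from .tables import (
    AGE_STANDARDIZED,
    AgeStandard,
    MEASURES,
    age_bin_midpoint,
    default_age_bins,
    validate_measure_table,
)

_EPS = 1e-6


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the standard study conditions.

    Key parameters
    --------------
    n_locations, years
        Panel dimensions (default 100 locations, the single year 2019).
    latent_alpha, latent_beta
        Beta distribution of per-location quality (default Beta(2, 2):
        symmetric, mid-concentrated).
    year_trend
        Additive drift of q per year after the first (default 0).
    mir_floor, mir_ceil
        Mortality-to-incidence ratio at perfect (q=1) and absent (q=0)
        care quality; mir = mir_floor + (mir_ceil - mir_floor) * (1 - q).
    duration_floor, duration_ceil
        Mean prevalent duration in years at q=0 and q=1; prevalence =
        incidence x duration.
    disability_weight
        YLD per prevalent case-year, in (0, 1).
    inc_scale, inc_midpoint_age, inc_steepness
        Logistic-in-age baseline incidence per 100,000: rises with age,
        half-maximum at ``inc_midpoint_age``.
    le_at_birth, le_at_top
        Residual life expectancy declines linearly from ``le_at_birth`` at
        age 0 to ``le_at_top`` at the open top bin; YLL = deaths x residual
        life expectancy at the bin midpoint.
    noise_sd
        Log-normal sigma of the multiplicative measure noise (default 0.1).
    sdi_noise_sd
        Gaussian noise on the q -> SDI link, truncated to [0, 1].
    sex_effect
        Multiplier on female latent quality (default 1.0 = no sex effect).
    independent_sex_noise
        Draw measure noise separately per sex (default False: shared, so
        sex differences come only from ``sex_effect``).
    """

    n_locations: int = 100
    years: Sequence[int] = (2019,)
    age_bins: Sequence[str] = field(default_factory=default_age_bins)
    latent_alpha: float = 2.0
    latent_beta: float = 2.0
    year_trend: float = 0.0
    sdi_intercept: float = 0.05
    sdi_slope: float = 0.9
    sdi_noise_sd: float = 0.05
    inc_scale: float = 300.0
    inc_midpoint_age: float = 65.0
    inc_steepness: float = 12.0
    mir_floor: float = 0.1
    mir_ceil: float = 0.9
    duration_floor: float = 1.0
    duration_ceil: float = 10.0
    disability_weight: float = 0.2
    le_at_birth: float = 85.0
    le_at_top: float = 2.0
    noise_sd: float = 0.1
    sex_effect: float = 1.0
    independent_sex_noise: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ConfigError("n_locations must be positive")
        if len(list(self.years)) < 1:
            raise ConfigError("years must be non-empty")
        if not (0 <= self.mir_floor < self.mir_ceil <= 1):
            raise ConfigError("need 0 <= mir_floor < mir_ceil <= 1")
        if not (0 < self.disability_weight < 1):
            raise ConfigError("disability_weight must lie in (0, 1)")
        if self.latent_alpha <= 0 or self.latent_beta <= 0:
            raise ConfigError("latent Beta parameters must be positive")
        if self.noise_sd < 0 or self.sdi_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.duration_floor <= 0 or self.duration_ceil <= self.duration_floor:
            raise ConfigError("need 0 < duration_floor < duration_ceil")
        if self.sex_effect <= 0:
            raise ConfigError("sex_effect must be positive")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["years"] = [int(y) for y in self.years]
        d["age_bins"] = list(self.age_bins)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # wrong types surfaced as config errors
            raise ConfigError(str(exc)) from exc

    # -- links -------------------------------------------------------------
    def mir_link(self, q: np.ndarray) -> np.ndarray:
        return self.mir_floor + (self.mir_ceil - self.mir_floor) * (1.0 - q)

    def duration_link(self, q: np.ndarray) -> np.ndarray:
        return self.duration_floor + (self.duration_ceil - self.duration_floor) * q

    def baseline_incidence(self, age_mid: np.ndarray) -> np.ndarray:
        return self.inc_scale / (
            1.0 + np.exp(-(age_mid - self.inc_midpoint_age) / self.inc_steepness)
        )

    def residual_life_expectancy(self, age_mid: np.ndarray) -> np.ndarray:
        top = age_bin_midpoint(list(self.age_bins)[-1])
        frac = np.clip(age_mid / top, 0.0, 1.0)
        return self.le_at_birth + (self.le_at_top - self.le_at_birth) * frac


def simulate_latent(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the latent quality/SDI table: one row per location-year-sex.

    Per-location quality comes from Beta(alpha, beta); a linear year trend
    and the female ``sex_effect`` multiplier are applied, and values are
    kept strictly inside (0, 1).  SDI is sexless: a monotone affine link of
    the location-year quality plus truncated noise.  ``sex = "both"`` rows
    carry the mean of the two sex-specific qualities.  Fixed seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    years = [int(y) for y in config.years]
    locs = [f"L{i:03d}" for i in range(config.n_locations)]
    q0 = rng.beta(config.latent_alpha, config.latent_beta, size=config.n_locations)
    q0 = np.clip(q0, _EPS, 1 - _EPS)

    rows = []
    for iy, year in enumerate(years):
        q_year = np.clip(q0 + config.year_trend * iy, _EPS, 1 - _EPS)
        sdi_noise = rng.normal(0.0, config.sdi_noise_sd, size=config.n_locations)
        sdi = np.clip(
            config.sdi_intercept + config.sdi_slope * q_year + sdi_noise, 0.0, 1.0
        )
        q_f = np.clip(q_year * config.sex_effect, _EPS, 1 - _EPS)
        q_m = q_year
        for sex, q in (("female", q_f), ("male", q_m), ("both", (q_f + q_m) / 2)):
            rows.append(
                pd.DataFrame(
                    {
                        "location": locs,
                        "year": year,
                        "sex": sex,
                        "q": q,
                        "sdi": sdi,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_measures(latent: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Generate the six-measure table from a latent table.

    Per sex-specific stratum and age bin: incidence from the baseline age
    curve; deaths = incidence x mir(q); prevalence = incidence x
    duration(q); YLD = prevalence x disability weight; YLL = deaths x
    residual life expectancy at the bin midpoint; DALY = YLL + YLD exactly.
    Log-normal noise is applied per measure from per-measure substreams, so
    adding a measure never shifts another's draws.  ``both``-sex rows are
    the mean of the two sexes; age-standardized rows are appended under the
    equal-weight reference standard.
    """
    age_bins = list(config.age_bins)
    age_mid = np.array([age_bin_midpoint(a) for a in age_bins])
    base_inc = config.baseline_incidence(age_mid)  # (A,)
    res_le = config.residual_life_expectancy(age_mid)

    years = sorted(latent["year"].unique())
    locs = sorted(latent[latent["sex"] == "male"]["location"].unique())
    L, Y, A = len(locs), len(years), len(age_bins)

    q = {
        sex: (
            latent[latent["sex"] == sex]
            .set_index(["location", "year"])["q"]
            .unstack("year")
            .reindex(index=locs, columns=years)
            .to_numpy()
        )
        for sex in ("female", "male")
    }
    sdi = (
        latent[latent["sex"] == "male"]
        .set_index(["location", "year"])["sdi"]
        .unstack("year")
        .reindex(index=locs, columns=years)
        .to_numpy()
    )

    # one deterministic substream per noisy measure
    noisy = ["incidence", "deaths", "prevalence", "yll", "yld"]
    children = np.random.SeedSequence(config.seed).spawn(1 + len(noisy))
    streams = {m: np.random.default_rng(ss) for m, ss in zip(noisy, children[1:])}
    n_sex_draws = 2 if config.independent_sex_noise else 1
    eps = {
        m: np.exp(
            streams[m].normal(0.0, config.noise_sd, size=(n_sex_draws, L, Y, A))
        )
        if config.noise_sd > 0
        else np.ones((n_sex_draws, L, Y, A))
        for m in noisy
    }

    def stratum_rates(sex: str, isex: int) -> dict[str, np.ndarray]:
        qi = q[sex][..., None]  # (L, Y, 1)
        e = {m: eps[m][isex if config.independent_sex_noise else 0] for m in noisy}
        inc0 = np.broadcast_to(base_inc, (L, Y, A))
        deaths0 = inc0 * config.mir_link(qi)
        prev0 = inc0 * config.duration_link(qi)
        yld0 = prev0 * config.disability_weight
        yll0 = deaths0 * res_le
        return {
            "incidence": inc0 * e["incidence"],
            "deaths": deaths0 * e["deaths"],
            "prevalence": prev0 * e["prevalence"],
            "yll": yll0 * e["yll"],
            "yld": yld0 * e["yld"],
        }

    rates = {
        "female": stratum_rates("female", 0),
        "male": stratum_rates("male", 1),
    }
    rates["both"] = {
        m: (rates["female"][m] + rates["male"][m]) / 2.0 for m in noisy
    }

    standard = AgeStandard.equal(age_bins)
    weights = np.array([standard.weights[a] for a in age_bins])

    # ASR for the five generated measures, then DALY = YLL + YLD at *every*
    # aggregation level so the identity holds exactly row-by-row
    asr = {sex: {m: rates[sex][m] @ weights for m in noisy} for sex in rates}
    for sex in rates:
        rates[sex]["daly"] = rates[sex]["yll"] + rates[sex]["yld"]
        asr[sex]["daly"] = asr[sex]["yll"] + asr[sex]["yld"]

    frames = []
    loc_idx = np.repeat(locs, Y * A)
    year_idx = np.tile(np.repeat(years, A), L)
    age_idx = np.tile(age_bins, L * Y)
    for sex in ("female", "male", "both"):
        for m in MEASURES:
            vals = rates[sex][m]
            frames.append(
                pd.DataFrame(
                    {
                        "location": loc_idx,
                        "year": year_idx,
                        "sex": sex,
                        "age_group": age_idx,
                        "measure": m,
                        "value": vals.reshape(-1),
                        "sdi": np.repeat(sdi.reshape(-1), A),
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "location": np.repeat(locs, Y),
                        "year": np.tile(years, L),
                        "sex": sex,
                        "age_group": AGE_STANDARDIZED,
                        "measure": m,
                        "value": asr[sex][m].reshape(-1),
                        "sdi": sdi.reshape(-1),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return validate_measure_table(table)


def truth_join(latent: pd.DataFrame, qci: pd.DataFrame) -> pd.DataFrame:
    """Inner-join latent truth with index scores on (location, year, sex).

    Raises when the join is empty; the caller can compare ``n_pairs`` =
    ``len(result)`` against ``len(latent)`` to detect partial overlap.
    """
    on = ["location", "year", "sex"]
    merged = latent.merge(qci, on=on, how="inner", suffixes=("_latent", ""))
    if merged.empty:
        raise InsufficientDataError("latent table and QCI table share no strata")
    return merged
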