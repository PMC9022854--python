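"""The PCA-based quality-of-care index (QCI).

The index is the leading principal component of the four secondary burden
ratios, oriented so that higher scores mean better care, then min-max
rescaled to [0, 100] over the fitting frame:

    qci(x) = 100 * (score(x) - min score) / (max score - min score)

where ``score(x)`` is the oriented projection of the (standardized) ratio
vector onto the first component.  By default the component is extracted from
the correlation matrix (z-scored ratios): the four ratios live on very
different scales (yll_yld commonly exceeds 10 while mir stays below 1), so
covariance PCA would let a single ratio dominate.  Covariance mode and a
natural-log pre-transform are available by flag and are recorded in the
fitted model so scoring always matches fitting.

Orientation is pinned to the mortality-to-incidence ratio: after applying
the orientation sign, the mir loading is non-positive, so raising mortality
(at fixed incidence and all else equal) can never raise the index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, InsufficientDataError
from .ratios import RATIO_COLUMNS

#: Eigenvalue gap below which the top two components count as tied.
_EIGEN_TIE_TOL = 1e-9


@dataclass
class QCIModel:
    """A fitted quality-of-care index.

    Attributes
    ----------
    means, scales
        Per-ratio centering and scaling constants (scales are all 1 in
        covariance mode), applied after the optional log transform.
    loadings
        Unit-norm first principal component over (mir, prev_inc, daly_prev,
        yll_yld), stored *before* orientation.
    orientation
        +1 or -1; the sign applied to the projection so that higher = better
        care (oriented mir loading <= 0).
    explained_fraction
        Leading eigenvalue divided by total variance, in (0, 1].
    score_min, score_max
        Extremes of the oriented raw scores over the fitting frame; the
        anchors of the 0-100 rescale.
    standardize, log_transform
        The preprocessing flags the model was fitted with.
    n_strata
        Number of strata in the fitting frame.
    eigen_tie_broken
        True when the top two eigenvalues were numerically tied and the
        component with the larger |mir| loading was selected.
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    orientation: int
    explained_fraction: float
    score_min: float
    score_max: float
    standardize: bool = True
    log_transform: bool = False
    n_strata: int = 0
    eigen_tie_broken: bool = False

    def oriented_loadings(self) -> np.ndarray:
        return self.orientation * self.loadings

    # -- flat key=value serialization for audit ---------------------------
    def to_file(self, path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    v = ",".join(f"{x:.17g}" for x in v)
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "QCIModel":
        raw: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.split("=", 1)
                    raw[k.strip()] = v.strip()
        vec = lambda s: np.array([float(x) for x in s.split(",")])
        return cls(
            means=vec(raw["means"]),
            scales=vec(raw["scales"]),
            loadings=vec(raw["loadings"]),
            orientation=int(raw["orientation"]),
            explained_fraction=float(raw["explained_fraction"]),
            score_min=float(raw["score_min"]),
            score_max=float(raw["score_max"]),
            standardize=raw["standardize"] == "True",
            log_transform=raw["log_transform"] == "True",
            n_strata=int(raw["n_strata"]),
            eigen_tie_broken=raw["eigen_tie_broken"] == "True",
        )


def orient_component(loadings: np.ndarray) -> int:
    """Sign that makes the component point toward better care.

    Returns -1 when the mir loading is positive, +1 when negative.  If the
    mir loading is exactly zero the decision falls to yll_yld, then
    daly_prev, then the negated prev_inc loading (prevalence-to-incidence is
    the one ratio where higher is better).
    """
    l = np.asarray(loadings, dtype=float)
    # tie-break chain: each entry is "higher is worse" on its scale
    for v in (l[0], l[3], l[2], -l[1]):
        if v > 0:
            return -1
        if v < 0:
            return +1
    raise DegenerateInputError("all loadings are zero; cannot orient component")


def _design_matrix(ratios: pd.DataFrame, log_transform: bool) -> np.ndarray:
    X = ratios[RATIO_COLUMNS].to_numpy(dtype=float)
    if log_transform:
        if np.any(X <= 0):
            raise DegenerateInputError(
                "log transform requires strictly positive ratios"
            )
        X = np.log(X)
    return X


def fit_qci(
    ratios: pd.DataFrame,
    standardize: bool = True,
    log_transform: bool = False,
) -> QCIModel:
    """Fit the index on a ratio table.

    The first principal component of the (optionally log-transformed,
    z-scored by default) four ratios is extracted; its explained fraction is
    the leading eigenvalue over the trace.  Needs at least 3 strata and
    nonzero variance in every ratio column.
    """
    n = len(ratios)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 strata to fit, got {n}")
    X = _design_matrix(ratios, log_transform)
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = np.isclose(sd, 0.0)
    if zero_var.any():
        bad = [RATIO_COLUMNS[i] for i in np.nonzero(zero_var)[0]]
        raise DegenerateInputError(f"zero-variance ratio column(s): {bad}")
    scales = sd if standardize else np.ones(4)
    Z = (X - means) / scales

    n_comp = min(2, n - 1, 4)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_[0]
    explained = float(pca.explained_variance_ratio_[0])
    tie_broken = False
    if n_comp >= 2:
        lam = pca.explained_variance_
        if lam[0] - lam[1] <= _EIGEN_TIE_TOL * max(lam[0], 1.0):
            # tied leading eigenvalues: deterministic pick by |mir| loading
            cand = pca.components_[:2]
            pick = int(np.argmax(np.abs(cand[:, 0])))
            loadings = cand[pick]
            explained = float(pca.explained_variance_ratio_[pick])
            tie_broken = True
    loadings = loadings / np.linalg.norm(loadings)
    orientation = orient_component(loadings)

    raw = orientation * (Z @ loadings)
    score_min, score_max = float(raw.min()), float(raw.max())
    if math.isclose(score_min, score_max):
        raise DegenerateInputError("raw scores have zero spread; cannot rescale")
    return QCIModel(
        means=means,
        scales=scales,
        loadings=loadings,
        orientation=orientation,
        explained_fraction=explained,
        score_min=score_min,
        score_max=score_max,
        standardize=standardize,
        log_transform=log_transform,
        n_strata=n,
        eigen_tie_broken=tie_broken,
    )


def explained_variance(model: QCIModel) -> float:
    """Share of total ratio variance captured by the index component."""
    return model.explained_fraction


def score_qci(
    model: QCIModel,
    ratios: pd.DataFrame,
    clamp: bool = False,
) -> pd.DataFrame:
    """Score strata with a fitted model.

    Returns the stratum key columns plus ``qci`` (full precision) and
    ``in_frame`` (False where the score falls outside [0, 100], which can
    happen for strata outside the fitting frame).  Out-of-frame scores are
    flagged, and clamped into [0, 100] only when ``clamp=True``.
    """
    if math.isclose(model.score_min, model.score_max):
        raise DegenerateInputError("model has degenerate rescale anchors")
    X = _design_matrix(ratios, model.log_transform)
    Z = (X - model.means) / model.scales
    raw = model.orientation * (Z @ model.loadings)
    qci = 100.0 * (raw - model.score_min) / (model.score_max - model.score_min)
    out = ratios.drop(columns=RATIO_COLUMNS).copy()
    out["qci"] = qci
    out["in_frame"] = (qci >= -1e-9) & (qci <= 100.0 + 1e-9)
    if clamp:
        out["qci"] = out["qci"].clip(0.0, 100.0)
    return out


def fit_and_score(
    ratios: pd.DataFrame,
    fit_scope: str = "pooled",
    standardize: bool = True,
    log_transform: bool = False,
    clamp: bool = False,
) -> tuple[pd.DataFrame, dict[str, QCIModel]]:
    """Fit and score in one step, optionally refitting per subgroup.

    ``fit_scope`` is one of ``pooled`` (one model over all strata),
    ``per_sex`` (refit within each sex), or ``per_age`` (refit within each
    age group).  Returns the scored table and the fitted model(s) keyed by
    scope label.
    """
    scopes = {"pooled": None, "per_sex": "sex", "per_age": "age_group"}
    if fit_scope not in scopes:
        raise DegenerateInputError(f"unknown fit_scope {fit_scope!r}")
    group_col = scopes[fit_scope]
    if group_col is None:
        model = fit_qci(ratios, standardize, log_transform)
        return score_qci(model, ratios, clamp=clamp), {"pooled": model}
    pieces, models = [], {}
    for label, grp in ratios.groupby(group_col, sort=True):
        model = fit_qci(grp, standardize, log_transform)
        models[str(label)] = model
        pieces.append(score_qci(model, grp, clamp=clamp))
    return pd.concat(pieces, ignore_index=True), models


def correlate_with_reference(
    qci: pd.DataFrame,
    reference: pd.DataFrame,
    on: list[str] | None = None,
    qci_col: str = "qci",
    ref_col: str = "value",
) -> tuple[float, int]:
    """Pearson correlation between index scores and a reference quality
    measure over matched strata.

    Returns ``(r, n_matched)``.  Needs at least 3 matched strata and nonzero
    variance in both series.
    """
    if on is None:
        on = [c for c in ("location", "year", "sex", "age_group") if c in qci.columns and c in reference.columns]
    merged = qci.merge(reference, on=on, how="inner", suffixes=("", "_ref"))
    ref_name = ref_col if ref_col in merged.columns else f"{ref_col}_ref"
    n = len(merged)
    if n < 3:
        raise InsufficientDataError(f"only {n} matched strata; need >= 3")
    x = merged[qci_col].to_numpy(dtype=float)
    y = merged[ref_name].to_numpy(dtype=float)
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise DegenerateInputError("zero variance; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), n
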