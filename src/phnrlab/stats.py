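"""Group-level statistics via linear generalized estimating equations.

Eyes are clustered within subjects (two eyes, repeated recordings), so
marginal linear models are fitted by GEE with a robust (sandwich)
covariance estimate and, by default, an exchangeable working correlation.
Wald z statistics use the two-sided normal reference.

The solver is delegated to :mod:`statsmodels`; this module owns the model
contracts: ON-status comparisons per ERG feature (optionally age-adjusted),
control-source contrasts, and structure-function regressions on HVF mean
deviation or OCT layer thicknesses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GEEFit",
    "StatsError",
    "fit_linear_gee",
    "compare_on_vs_control",
    "compare_control_sources",
    "structure_function_models",
    "fits_to_frame",
]

DEFAULT_FEATURES = ["phnr_min_uv", "phnr72_uv", "p_ratio", "w_ratio"]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GEEFit:
    coefficient_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    robust_se: tuple[float, ...]
    wald_z: tuple[float, ...]
    p_values: tuple[float, ...]
    working_correlation: str
    exchangeable_alpha: float | None
    n_clusters: int
    n_observations: int

    def coef(self, name: str) -> float:
        return self.coefficients[self.coefficient_names.index(name)]

    def se(self, name: str) -> float:
        return self.robust_se[self.coefficient_names.index(name)]

    def p(self, name: str) -> float:
        return self.p_values[self.coefficient_names.index(name)]


def fit_linear_gee(response, design: pd.DataFrame, cluster_ids,
                   correlation: str = "exchangeable") -> GEEFit:
    """Linear GEE of ``response`` on ``design`` (must include an intercept
    column) with clusters ``cluster_ids`` and robust standard errors."""
    if correlation not in ("independence", "exchangeable"):
        raise StatsError(f"unknown working correlation {correlation!r}")
    y = np.asarray(response, dtype=float)
    X = design.astype(float)
    groups = np.asarray(cluster_ids)
    if np.unique(groups).size < 2:
        raise StatsError("GEE requires at least 2 clusters")
    if np.isnan(y).any() or X.isna().to_numpy().any():
        raise StatsError("missing values must be removed before fitting")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise StatsError("singular design matrix")
    cov = sm.cov_struct.Exchangeable() if correlation == "exchangeable" \
        else sm.cov_struct.Independence()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y, X, groups=groups, family=sm.families.Gaussian(),
                       cov_struct=cov)
        result = model.fit()
    coef = np.asarray(result.params, dtype=float)
    se = np.asarray(result.bse, dtype=float)  # robust sandwich SE by default
    z = coef / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    alpha = float(cov.dep_params) if correlation == "exchangeable" else None
    return GEEFit(
        coefficient_names=tuple(X.columns),
        coefficients=tuple(coef), robust_se=tuple(se),
        wald_z=tuple(z), p_values=tuple(p),
        working_correlation=correlation, exchangeable_alpha=alpha,
        n_clusters=int(np.unique(groups).size), n_observations=int(y.size),
    )


def _labeled(features: pd.DataFrame) -> pd.DataFrame:
    df = features[features["label"].isin(["ON_POS", "ON_NEG"])]
    if df.empty:
        raise StatsError("no labeled eyes in the feature table")
    return df


def _fit_per_feature(df: pd.DataFrame, columns: list[str], design_cols: dict,
                     correlation: str) -> dict[str, GEEFit]:
    """One GEE per feature with listwise deletion per model."""
    fits: dict[str, GEEFit] = {}
    for feat in columns:
        if feat not in df.columns:
            warnings.warn(f"feature column {feat!r} missing; skipped")
            continue
        cols = {"intercept": 1.0, **design_cols}
        sub = df.dropna(subset=[feat] + [c for c in design_cols.values()
                                         if isinstance(c, str)])
        design = pd.DataFrame(index=sub.index)
        for name, src in cols.items():
            design[name] = sub[src] if isinstance(src, str) else src
        fits[feat] = fit_linear_gee(sub[feat], design, sub["subject_id"], correlation)
    if not fits:
        raise StatsError("no feature columns available to model")
    return fits


def compare_on_vs_control(features: pd.DataFrame, adjust_age: bool = False,
                          feature_columns: list[str] | None = None,
                          correlation: str = "exchangeable") -> dict[str, GEEFit]:
    """Per-feature GEE of feature on ON status (indicator ``on``), clusters =
    subjects, optionally adjusted for age."""
    df = _labeled(features).copy()
    df["on"] = (df["label"] == "ON_POS").astype(float)
    design = {"on": "on"}
    if adjust_age:
        design["age_years"] = "age_years"
    return _fit_per_feature(df, feature_columns or DEFAULT_FEATURES, design, correlation)


def compare_control_sources(features: pd.DataFrame,
                            feature_columns: list[str] | None = None,
                            correlation: str = "exchangeable"
                            ) -> dict[str, dict[str, GEEFit]]:
    """Among control eyes, contrast each control source against the rest:
    fellow vs other controls, healthy vs other controls."""
    df = features[features["label"] == "ON_NEG"].copy()
    subtypes = set(df["eye_class"].unique())
    if len(subtypes) < 2:
        raise StatsError("control-source contrast needs at least 2 control subtypes")
    out: dict[str, dict[str, GEEFit]] = {}
    for contrast, cls in (("fellow_vs_other", "control_fellow"),
                          ("healthy_vs_other", "control_healthy")):
        sub = df.copy()
        sub[contrast] = (sub["eye_class"] == cls).astype(float)
        if sub[contrast].nunique() < 2:
            continue
        out[contrast] = _fit_per_feature(sub, feature_columns or DEFAULT_FEATURES,
                                         {contrast: contrast}, correlation)
    if not out:
        raise StatsError("no estimable control-source contrast")
    return out


_PREDICTOR_COLS = {"hvf_md": "hvf_md_db", "rnfl": "rnfl_um", "gclipl": "gclipl_um"}


def structure_function_models(features: pd.DataFrame, predictor: str,
                              eye_classes: list[str] | None = None,
                              feature_columns: list[str] | None = None,
                              correlation: str = "exchangeable",
                              min_eyes: int = 10) -> dict[str, GEEFit]:
    """Per-feature linear GEE of feature on a structural/functional measure.

    OCT predictors (rnfl, gclipl) exclude acute ON eyes by default, since
    acute disc swelling inflates layer thickness.
    """
    if predictor not in _PREDICTOR_COLS:
        raise StatsError(f"unknown predictor {predictor!r}")
    col = _PREDICTOR_COLS[predictor]
    df = _labeled(features).copy()
    if eye_classes is None and predictor in ("rnfl", "gclipl"):
        eye_classes = ["on_chronic", "control_fellow", "control_patient",
                       "control_healthy"]
    if eye_classes is not None:
        df = df[df["eye_class"].isin(eye_classes)]
    df = df.dropna(subset=[col])
    if df.empty:
        raise StatsError(f"empty subset for predictor {predictor}")
    if len(df) < min_eyes:
        raise StatsError(f"predictor {predictor} available for only {len(df)} eyes "
                         f"(minimum {min_eyes})")
    return _fit_per_feature(df, feature_columns or DEFAULT_FEATURES,
                            {col: col}, correlation)


def fits_to_frame(fits: dict[str, GEEFit], model: str = "") -> pd.DataFrame:
    """Tidy per-term table (model, feature, term, estimate, robust_se, z, p)."""
    rows = []
    for feat, fit in fits.items():
        for name, c, s, z, p in zip(fit.coefficient_names, fit.coefficients,
                                    fit.robust_se, fit.wald_z, fit.p_values):
            rows.append({"model": model, "feature": feat, "term": name,
                         "estimate": c, "robust_se": s, "z": z, "p": p,
                         "n_clusters": fit.n_clusters,
                         "n_observations": fit.n_observations})
    return pd.DataFrame(rows)
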