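"""Adjusted regression of regional SUVr on log tract-WMH burden.

For each tract-region pair the model

    SUVr_region = b0 + b1 * log10(WMH volume in tract) + bX . covariates + e

is fit by ordinary least squares with covariates age, sex, ApoE e4 allele
count and total intracranial volume. The family of four pairwise tests
(SLF-IPL, IFOF-MPFC, CING-PCC, CING_Hippo-MTL) is Bonferroni-controlled:
with alpha = .05 the per-test significance threshold is .05/4 = .0125.

Reported per pair: standardized beta, two-sided p for b1, 95% t-based CI on
b1, adjusted R-squared, Cohen's f effect size, and the analyzed n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, InputError
from .phantom import REGION_FOR_TRACT

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "fit_adjusted_model",
    "standardized_beta",
    "adjusted_r2",
    "cohens_f",
    "bonferroni_threshold",
    "run_family",
    "RESULT_COLUMNS",
]

DEFAULT_COVARIATES = ("age", "sex", "apoe_e4_count", "icv")

RESULT_COLUMNS = [
    "region",
    "tract",
    "std_beta",
    "p_value",
    "adj_r2",
    "ci_low",
    "ci_high",
    "cohens_f",
    "n_used",
    "significant",
]


@dataclass(frozen=True)
class ModelSpec:
    """One tract-region model: outcome and predictor column names + family control."""

    outcome: str
    predictor: str
    tract: str = ""
    region: str = ""
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    family_size: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise InputError(f"family_size must be >= 1, got {self.family_size}")
        if not 0 < self.alpha <= 1:
            raise InputError(f"alpha must be in (0,1], got {self.alpha}")


@dataclass
class AssociationResult:
    """Fitted statistics for one tract-region model."""

    tract: str
    region: str
    b0: float
    b1: float
    bX: dict[str, float]
    std_beta: float
    p_value: float
    ci_low: float
    ci_high: float
    adj_r2: float
    r2: float
    cohens_f: float
    n_used: int
    significant: bool

    def to_row(self) -> dict:
        return {
            "region": self.region,
            "tract": self.tract,
            "std_beta": self.std_beta,
            "p_value": self.p_value,
            "adj_r2": self.adj_r2,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cohens_f": self.cohens_f,
            "n_used": self.n_used,
            "significant": self.significant,
        }


def standardized_beta(b1: float, sd_predictor: float, sd_outcome: float) -> float:
    """Slope rescaled to outcome-SDs per predictor-SD: b1 * sd_x / sd_y."""
    if sd_predictor <= 0 or sd_outcome <= 0:
        raise EstimationError(
            f"standardized beta needs positive SDs, got sd_x={sd_predictor}, sd_y={sd_outcome}"
        )
    return b1 * sd_predictor / sd_outcome


def adjusted_r2(r2: float, n: int, p_predictors: int) -> float:
    """Adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1); may be negative near R^2=0."""
    if not 0 <= r2 <= 1:
        raise InputError(f"r2 must be in [0,1], got {r2}")
    if n <= p_predictors + 1:
        raise InputError(f"n={n} too small for {p_predictors} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_predictors - 1)


def cohens_f(adj_r2_value: float) -> float:
    """Cohen's f = sqrt(R^2 / (1 - R^2)) from the adjusted R^2.

    Negative adjusted R^2 (possible on null data) is clamped to 0 so the
    effect size stays real-valued.
    """
    if adj_r2_value >= 1:
        raise InputError(f"adjusted R^2 must be < 1, got {adj_r2_value}")
    r2 = max(adj_r2_value, 0.0)
    return float(np.sqrt(r2 / (1.0 - r2)))


def bonferroni_threshold(alpha: float = 0.05, m: int = 4) -> float:
    """Per-test significance threshold alpha/m for an m-test family."""
    if not 0 < alpha <= 1:
        raise InputError(f"alpha must be in (0,1], got {alpha}")
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    return alpha / m


def fit_adjusted_model(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one adjusted OLS model and assemble its reported statistics.

    Rows with missing values in the outcome, predictor or covariates are
    dropped (listwise deletion). The p-value on b1 is two-sided from the t
    distribution with n - p - 1 degrees of freedom; the 95% CI likewise.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise InputError(f"data table lacks columns {missing}")
    df = data[cols].dropna()
    n = len(df)
    p = 1 + len(spec.covariates)
    if n <= p + 1:
        raise EstimationError(f"n_used={n} too small to fit {p} predictors")
    y = df[spec.outcome].to_numpy(dtype=float)
    x = df[spec.predictor].to_numpy(dtype=float)
    if np.std(y, ddof=1) == 0:
        raise EstimationError(f"outcome {spec.outcome!r} is constant on analyzed rows")
    if np.std(x, ddof=1) == 0:
        raise EstimationError(f"predictor {spec.predictor!r} is constant on analyzed rows")
    X = sm.add_constant(df[[spec.predictor, *spec.covariates]].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise EstimationError("design matrix is rank deficient (collinear covariates?)")
    res = sm.OLS(y, X).fit()
    b1 = float(res.params[spec.predictor])
    ci = res.conf_int(alpha=0.05)
    sb = standardized_beta(b1, float(np.std(x, ddof=1)), float(np.std(y, ddof=1)))
    adj = float(res.rsquared_adj)
    # a perfect (noise-free) fit has adj R^2 == 1; report an infinite effect
    # size rather than rejecting the fit outright
    f_effect = float("inf") if adj >= 1.0 else cohens_f(adj)
    return AssociationResult(
        tract=spec.tract,
        region=spec.region,
        b0=float(res.params["const"]),
        b1=b1,
        bX={c: float(res.params[c]) for c in spec.covariates},
        std_beta=sb,
        p_value=float(res.pvalues[spec.predictor]),
        ci_low=float(ci.loc[spec.predictor, 0]),
        ci_high=float(ci.loc[spec.predictor, 1]),
        adj_r2=adj,
        r2=float(res.rsquared),
        cohens_f=f_effect,
        n_used=n,
        significant=bool(
            res.pvalues[spec.predictor] < bonferroni_threshold(spec.alpha, spec.family_size)
        ),
    )


def run_family(
    suvr: pd.DataFrame,
    tract_volumes: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: dict[str, str] | None = None,
    alpha: float = 0.05,
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Fit the whole tract-region family and return a Table-3-shaped frame.

    ``suvr`` is long (subject_id, region_name, suvr[, included]);
    ``tract_volumes`` is long (subject_id, tract_name, log_volume[, included]);
    ``covariates`` is wide per subject. Rows flagged ``included=False`` by
    the upstream floors/policies are dropped before fitting. A pair that
    cannot be estimated is reported with NaN statistics and a warning; other
    pairs are unaffected.
    """
    pairs = dict(pairs) if pairs is not None else dict(REGION_FOR_TRACT)
    m = len(pairs)
    rows = []
    for tract, region in pairs.items():
        s = suvr[suvr["region_name"] == region]
        if "included" in s.columns:
            s = s[s["included"]]
        t = tract_volumes[tract_volumes["tract_name"] == tract]
        if "included" in t.columns:
            t = t[t["included"]]
        merged = (
            s[["subject_id", "suvr"]]
            .merge(t[["subject_id", "log_volume"]], on="subject_id")
            .merge(covariates, on="subject_id")
        )
        spec = ModelSpec(
            outcome="suvr",
            predictor="log_volume",
            tract=tract,
            region=region,
            covariates=covariate_names,
            family_size=m,
            alpha=alpha,
        )
        try:
            rows.append(fit_adjusted_model(merged, spec).to_row())
        except EstimationError as exc:
            warnings.warn(f"pair {tract}->{region} not estimable: {exc}", stacklevel=2)
            rows.append(
                {
                    "region": region,
                    "tract": tract,
                    "std_beta": np.nan,
                    "p_value": np.nan,
                    "adj_r2": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "cohens_f": np.nan,
                    "n_used": len(merged),
                    "significant": False,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
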