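"""Ancestry stratification and trait–trait correlation on synthetic cohorts.

In admixed cohorts (e.g. mixed African/European ancestry), any two traits
that each track ancestry — hair curvature, cross-sectional eccentricity,
melanin index — are marginally correlated even with no direct link between
them. This module synthesizes such cohorts with a configurable *direct*
eccentricity→curvature effect (default 0), and provides the regression
machinery to demonstrate that the marginal association vanishes once the
ancestry proportion enters the model:

* quadratic or linear fits ``y = α + β₀x (+ β₁x²)`` and ancestry-adjusted
  fits ``y = α + β₀x + β₁z``;
* optional weighted refit with weights 1/ŷᵢ² taken from the unweighted
  pass (the cohorts are heteroscedastic: trait variance grows with African
  ancestry);
* the residual-on-residual construction: regress each trait on ancestry and
  associate the residuals.

Also includes ordinal binning of continuous curvature against user-supplied
thresholds (the conventional curl-type thresholds come from external
published work and are deliberately not hard-coded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CohortConfig",
    "RegressionResult",
    "synth_cohort",
    "fit_model",
    "ancestry_corrected_association",
    "bin_curvature",
    "stratification_demo",
]


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic admixed-cohort generative parameters.

    Ancestry proportion z is a 50/50 Beta(2,5)/Beta(5,2) mixture spanning
    [0, 1] (a bimodal admixed-cohort shape). Each trait is a monotone
    function of z plus heteroscedastic Gaussian noise with SD
    ``c0 + c1·z`` (variance grows with African ancestry). ``direct_effect``
    adds a true eccentricity→curvature effect (per unit centered
    eccentricity); the default 0 means any marginal curvature–eccentricity
    association is pure stratification.
    """

    # curvature (mm^-1): straight-ish at z=0 to tightly curled at z=1
    curvature_intercept: float = 0.2
    curvature_slope: float = 1.2
    curvature_noise: tuple[float, float] = (0.05, 0.25)
    # cross-sectional eccentricity (dimensionless)
    eccentricity_intercept: float = 0.45
    eccentricity_slope: float = 0.25
    eccentricity_noise: tuple[float, float] = (0.03, 0.07)
    # melanin index (reflectance units)
    melanin_intercept: float = 30.0
    melanin_slope: float = 40.0
    melanin_noise: tuple[float, float] = (2.0, 6.0)
    direct_effect: float = 0.0


@dataclass
class RegressionResult:
    """Coefficients, SEs, p-values, residuals and the weights used."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    weighted: bool
    weights: np.ndarray | None = None


def synth_cohort(n: int = 140, config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate an admixed cohort with ancestry-driven, heteroscedastic
    traits and (by default) no direct trait–trait coupling.

    Returns columns ``ancestry``, ``melanin_index``, ``curvature``,
    ``eccentricity``. Deterministic given (n, config, seed).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    cfg = config or CohortConfig()
    for c0, c1 in (cfg.curvature_noise, cfg.eccentricity_noise, cfg.melanin_noise):
        if c0 < 0 or c1 < 0:
            raise ValueError("noise scales must be nonnegative")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.5
    z = np.where(comp, rng.beta(2, 5, n), rng.beta(5, 2, n))

    def trait(intercept, slope, noise):
        sd = noise[0] + noise[1] * z
        return intercept + slope * z + rng.normal(0.0, 1.0, n) * sd

    ecc = np.clip(trait(cfg.eccentricity_intercept, cfg.eccentricity_slope, cfg.eccentricity_noise), 0.0, 0.99)
    curv = trait(cfg.curvature_intercept, cfg.curvature_slope, cfg.curvature_noise)
    curv = curv + cfg.direct_effect * (ecc - ecc.mean())
    curv = np.clip(curv, 0.0, None)
    mel = trait(cfg.melanin_intercept, cfg.melanin_slope, cfg.melanin_noise)
    return pd.DataFrame(
        {"ancestry": z, "melanin_index": mel, "curvature": curv, "eccentricity": ecc}
    )


def fit_model(
    y,
    x,
    covariate=None,
    form: str = "linear",
    weighted: bool = False,
) -> RegressionResult:
    """OLS fit of y on x (optionally + x² and/or an ancestry covariate),
    with an optional weighted second pass.

    ``form="quadratic"`` fits ``y = α + β₀x + β₁x²``; ``form="linear"``
    fits ``y = α + β₀x (+ β₁z)``. With ``weighted=True`` the model is refit
    by WLS with weights 1/ŷᵢ², where ŷᵢ are fitted values from the
    unweighted pass; with equal fitted values the two passes coincide.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    cols = {"x": x}
    if form == "quadratic":
        cols["x2"] = x * x
    elif form != "linear":
        raise ValueError(f"unknown form {form!r}")
    if covariate is not None:
        cols["z"] = np.asarray(covariate, float)
    X = sm.add_constant(pd.DataFrame(cols))
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    ols = sm.OLS(y, X).fit()
    if not weighted:
        return RegressionResult(
            params=ols.params, bse=ols.bse, pvalues=ols.pvalues,
            residuals=np.asarray(ols.resid), fitted=np.asarray(ols.fittedvalues),
            weighted=False,
        )
    fitted = np.asarray(ols.fittedvalues)
    if np.any(fitted == 0):
        raise ValueError("zero fitted value; 1/fitted^2 weights undefined")
    w = 1.0 / fitted**2
    wls = sm.WLS(y, X, weights=w).fit()
    return RegressionResult(
        params=wls.params, bse=wls.bse, pvalues=wls.pvalues,
        residuals=np.asarray(wls.resid), fitted=np.asarray(wls.fittedvalues),
        weighted=True, weights=w,
    )


def ancestry_corrected_association(trait_a, trait_b, ancestry) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Residual-on-residual association after removing ancestry.

    Each trait is regressed on ancestry; the function returns
    ``(residuals_a, residuals_b, slope, p)`` where slope and p come from the
    OLS regression of the b-residuals on the a-residuals. Under pure
    stratification (no direct effect) the residual slope is null.
    """
    trait_a = np.asarray(trait_a, float)
    trait_b = np.asarray(trait_b, float)
    res_a = fit_model(trait_a, ancestry).residuals
    res_b = fit_model(trait_b, ancestry).residuals
    fit = fit_model(res_b, res_a)
    return res_a, res_b, float(fit.params["x"]), float(fit.pvalues["x"])


def bin_curvature(curvatures, thresholds) -> np.ndarray:
    """Assign ordinal class labels (1-based) to curvature values.

    ``thresholds`` must be strictly increasing; intervals are half-open
    ``[t_k, t_{k+1})``, so a value exactly at a threshold goes to the upper
    bin. An empty threshold list puts everything in bin 1.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return np.digitize(np.asarray(curvatures, float), thresholds, right=False) + 1


def stratification_demo(
    n: int = 140,
    n_seeds: int = 100,
    config: CohortConfig | None = None,
    base_seed: int = 0,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Monte Carlo stratification demonstration over ``n_seeds`` cohorts.

    For each seeded cohort: the marginal curvature~eccentricity association
    (linear OLS) and the ancestry-adjusted residual association are both
    tested at level ``alpha``. Returns one row per cohort with slopes and
    p-values; with a default (zero direct effect) config, the marginal
    association is expected significant and the adjusted one null in the
    bulk of cohorts.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cohort = synth_cohort(n=n, config=config, seed=seed)
        marginal = fit_model(cohort["curvature"], cohort["eccentricity"])
        _, _, slope, p_adj = ancestry_corrected_association(
            cohort["eccentricity"], cohort["curvature"], cohort["ancestry"]
        )
        rows.append(
            {
                "seed": seed,
                "marginal_slope": float(marginal.params["x"]),
                "marginal_p": float(marginal.pvalues["x"]),
                "adjusted_slope": slope,
                "adjusted_p": p_adj,
                "marginal_significant": bool(marginal.pvalues["x"] < alpha),
                "adjusted_significant": bool(p_adj < alpha),
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "stratification_demo.csv", index=False)
    return df
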