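"""Allometric scaling and comparison statistics.

Scaling relationships are fit on log10-log10 axes with linear
mixed-effects models in which species contribute random intercepts and
slopes around a population-level (fixed) power law; the fixed slope is
the scaling exponent of interest.  Goodness of fit is summarised by the
Nakagawa *marginal* R^2 — the share of variance explained by the fixed
effects alone.  Feeding-status comparisons use a two-way ANOVA on
log10 values (mass x status interaction tests slope differences, the
status main effect tests intercept differences), and distributional
comparisons of speed and turning use two-sided Wilcoxon rank-sum tests
with an exact small-sample path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

logger = logging.getLogger(__name__)


@dataclass
class ScalingFit:
    """Fixed-effect scaling exponent and variance decomposition."""

    fixed_slope: float
    fixed_intercept: float
    slope_ci95: tuple[float, float]
    marginal_r2: float
    var_fixed: float
    var_random: float
    var_residual: float
    converged: bool
    re_structure: str  # "correlated" | "uncorrelated" | "intercept-only"


def _validate_scaling_data(df, outcome_col, mass_col, species_col):
    if (df[mass_col] <= 0).any() or (df[outcome_col] <= 0).any():
        raise ValueError("mass and outcome must be > 0 for log10 transform")
    counts = df.groupby(species_col).size()
    if len(counts) < 2:
        raise ValueError("need >= 2 species")
    if (counts < 3).any():
        raise ValueError("need >= 3 observations per species")


def fit_allometric_mixed(
    data: pd.DataFrame,
    outcome_col: str = "outcome",
    mass_col: str = "mass_kg",
    species_col: str = "species",
) -> ScalingFit:
    """REML mixed-effects fit of log10(outcome) on log10(mass).

    The primary model carries correlated species-level random intercepts
    and slopes.  On non-convergence it falls back to uncorrelated random
    effects, then to a random intercept only, logging each step; if every
    structure fails an error is raised.  The marginal R^2 follows
    Nakagawa: var_fixed / (var_fixed + var_random + var_residual), with
    the random-effect variance evaluated at the design's mean covariate.
    """
    _validate_scaling_data(data, outcome_col, mass_col, species_col)
    y = np.log10(data[outcome_col].to_numpy(dtype=float))
    x = np.log10(data[mass_col].to_numpy(dtype=float))
    groups = data[species_col].to_numpy()
    exog = sm.add_constant(x)

    # degenerate (exactly collinear) data has no residual variance for the
    # mixed model to work with; report the exact line directly
    ols = sm.OLS(y, exog).fit()
    if ols.ssr / max(len(y), 1) < 1e-12:
        slope = float(ols.params[1])
        return ScalingFit(
            fixed_slope=slope,
            fixed_intercept=float(ols.params[0]),
            slope_ci95=(slope, slope),
            marginal_r2=1.0,
            var_fixed=float(np.var(exog @ ols.params)),
            var_random=0.0,
            var_residual=0.0,
            converged=True,
            re_structure="degenerate-ols",
        )

    ladder = [
        ("correlated", None, exog),
        (
            "uncorrelated",
            MixedLMParams.from_components(fe_params=np.ones(2), cov_re=np.eye(2)),
            exog,
        ),
        ("intercept-only", None, exog[:, :1]),
    ]
    last_err = None
    for structure, free, exog_re in ladder:
        res = None
        for method in ("lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = MixedLM(y, exog, groups=groups, exog_re=exog_re)
                    cand = model.fit(reml=True, free=free, method=method)
                    bse_fe = np.asarray(cand.bse_fe)
                if not np.all(np.isfinite(cand.fe_params)) or not np.all(np.isfinite(bse_fe)):
                    raise RuntimeError("non-finite fixed-effect estimates")
                if not cand.converged:
                    raise RuntimeError("optimizer did not converge")
                res = cand
                break
            except Exception as err:
                last_err = err
        if res is None:  # try the next, simpler structure
            logger.info("mixed model (%s) failed (%s); falling back", structure, last_err)
            continue
        if structure != "correlated":
            logger.warning("mixed model fit with fallback random-effect structure: %s", structure)
        intercept, slope = res.fe_params[:2]
        se = bse_fe[1]
        ci = (slope - 1.96 * se, slope + 1.96 * se)
        var_fixed = float(np.var(exog @ res.fe_params))
        zbar = np.array([1.0, float(np.mean(x))])[: exog_re.shape[1]]
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        var_random = float(zbar @ cov_re @ zbar)
        var_resid = float(res.scale)
        denom = var_fixed + var_random + var_resid
        r2m = var_fixed / denom if denom > 0 else np.nan
        return ScalingFit(
            fixed_slope=float(slope),
            fixed_intercept=float(intercept),
            slope_ci95=(float(ci[0]), float(ci[1])),
            marginal_r2=float(r2m),
            var_fixed=var_fixed,
            var_random=var_random,
            var_residual=var_resid,
            converged=True,
            re_structure=structure,
        )
    raise RuntimeError(f"all mixed-model structures failed to converge: {last_err}")


@dataclass
class FeedingComparison:
    """Two-way ANOVA of log10 FMR on log10 mass x feeding status."""

    interaction_F: float
    interaction_p: float
    status_F: float
    status_p: float
    slope_by_status: dict[str, float]
    intercept_offset: float  # status coefficient of the additive model
    alpha: float = 0.05

    @property
    def slopes_differ(self) -> bool:
        return self.interaction_p < self.alpha

    @property
    def intercepts_differ(self) -> bool:
        return self.status_p < self.alpha


def compare_feeding_scaling(
    data: pd.DataFrame,
    outcome_col: str = "outcome",
    mass_col: str = "mass_kg",
    status_col: str = "feeding_status",
) -> FeedingComparison:
    """Test whether foraging and non-foraging scaling lines differ.

    The full model ``log10 y ~ log10 M * status`` is compared against the
    additive model to test the interaction (slope difference); the
    additive model against ``log10 y ~ log10 M`` for the status main
    effect (intercept difference).  Fixed-effects OLS on log10 values.
    """
    statuses = sorted(data[status_col].unique())
    if len(statuses) < 2:
        raise ValueError("need both feeding statuses for the comparison")
    df = pd.DataFrame(
        {
            "ly": np.log10(data[outcome_col].to_numpy(dtype=float)),
            "lm": np.log10(data[mass_col].to_numpy(dtype=float)),
            "status": data[status_col].to_numpy(),
        }
    )
    full = smf.ols("ly ~ lm * C(status)", df).fit()
    additive = smf.ols("ly ~ lm + C(status)", df).fit()
    mass_only = smf.ols("ly ~ lm", df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        inter = sm.stats.anova_lm(additive, full)
        main = sm.stats.anova_lm(mass_only, additive)
    slopes = {}
    base = statuses[0]
    slopes[base] = float(full.params["lm"])
    for s in statuses[1:]:
        key = f"lm:C(status)[T.{s}]"
        slopes[s] = float(full.params["lm"] + full.params.get(key, 0.0))
    offset_key = f"C(status)[T.{statuses[1]}]"
    return FeedingComparison(
        interaction_F=float(inter["F"].iloc[1]),
        interaction_p=float(inter["Pr(>F)"].iloc[1]),
        status_F=float(main["F"].iloc[1]),
        status_p=float(main["Pr(>F)"].iloc[1]),
        slope_by_status=slopes,
        intercept_offset=float(additive.params.get(offset_key, 0.0)),
    )


def _ranksum_null_counts(nx: int, N: int) -> np.ndarray:
    """Number of ways to pick nx distinct ranks from 1..N with each sum.

    Dynamic programme over ranks; index s of the returned vector is the
    count of subsets whose rank-sum equals s.
    """
    max_sum = N * (N + 1) // 2
    counts = np.zeros((nx + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, nx), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    return counts[nx]


def wilcoxon_compare(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank-sum of ``x`` in the pooled sample (average ranks on
    ties).  When ``min(n_x, n_y) <= exact_max_n`` and there are no ties,
    the p-value sums the exact null distribution of the rank-sum
    (symmetric two-sided: P(|W' - mu| >= |W - mu|)); otherwise a normal
    approximation with tie correction is used (identical samples give
    z = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    N = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:nx].sum())
    mu = nx * (N + 1) / 2.0
    has_ties = np.unique(pooled).size < N
    if min(nx, ny) <= exact_max_n and not has_ties:
        counts = _ranksum_null_counts(nx, N)
        sums = np.arange(counts.size)
        dev = abs(W - mu)
        p = counts[np.abs(sums - mu) >= dev - 1e-9].sum() / comb(N, nx)
        return W, float(min(1.0, p))
    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    var = nx * ny / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return W, 1.0
    z = (W - mu) / np.sqrt(var)
    return W, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def metabolic_scope(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-whale foraging:non-foraging FMR ratios with species summaries.

    ``pairs`` needs columns ``whale_id``, ``species``, ``foraging`` and
    ``non_foraging`` (median FMRs).  Whales missing either estimate are
    excluded (logged).  Returns (per-whale table with ratio and an
    ``outlier`` flag at 1.5 x IQR within species, per-species summary
    with median and quartiles of the ratio).
    """
    required = {"whale_id", "species", "foraging", "non_foraging"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    ok = pairs["foraging"].notna() & pairs["non_foraging"].notna()
    dropped = pairs.loc[~ok, "whale_id"].tolist()
    if dropped:
        logger.info("excluding whales without a paired estimate: %s", dropped)
    df = pairs.loc[ok].copy()
    if df.empty:
        raise ValueError("no whales with paired foraging/non-foraging estimates")
    df["ratio"] = df["foraging"] / df["non_foraging"]
    df["outlier"] = False
    summaries = []
    for sp, grp in df.groupby("species"):
        q1, med, q3 = np.percentile(grp["ratio"], [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        df.loc[grp.index, "outlier"] = (grp["ratio"] < lo) | (grp["ratio"] > hi)
        summaries.append(
            {"species": sp, "n": len(grp), "median_ratio": med, "q1": q1, "q3": q3}
        )
    return df.reset_index(drop=True), pd.DataFrame(summaries)
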