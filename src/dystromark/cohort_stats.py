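"""Mixed-model statistics for longitudinal and post-mortem cohorts.

The modelling layer mirrors a two-genotype natural-history design: each
biomarker is analysed with a linear mixed model with fixed effects for
group, repeated level (age for longitudinal data, muscle for post-mortem
panels) and their interaction, and a random intercept per animal.  A
log10 transform is chosen per biomarker when Shapiro-Wilk normality
testing favours it.  Post-hoc group contrasts are evaluated within each
repeated level with model-based standard errors and corrected across the
level family by the Holm-Šídák step-down procedure; adjusted p-values map
to the conventional significance bands (* to **** at 0.05 / 0.01 / 0.001 /
0.0001).

The mixed model itself is fitted with statsmodels; the Holm-Šídák
correction, transform rule, banding and contrast machinery are implemented
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

ALPHA_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_band(p: float) -> str:
    """Map an (adjusted) p-value to the star convention; 'ns' otherwise."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    for cut, stars in ALPHA_BANDS:
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Multiple-comparison correction
# ---------------------------------------------------------------------------

def holm_sidak(pvals) -> np.ndarray:
    """Holm-Šídák step-down adjusted p-values, returned in input order.

    With the m raw p-values sorted ascending, the k-th adjusted value is
    ``max_{j<=k} [1 − (1 − p_(j))^(m − j + 1)]``, clipped to 1: each step
    applies the Šídák correction for the comparisons still in play, and the
    running maximum enforces monotonicity.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Transform selection
# ---------------------------------------------------------------------------

@dataclass
class TransformDecision:
    transform: str  # "identity" | "log10"
    cell_pvals: pd.DataFrame = field(repr=False)
    reason: str = ""


def choose_transform(
    data: pd.DataFrame,
    value_col: str = "value",
    cell_cols=("group", "level"),
    alpha: float = 0.05,
    min_cell_n: int = 3,
) -> TransformDecision:
    """Decide once per biomarker between raw and log10 analysis scales.

    Shapiro-Wilk normality is tested within every (group, level) cell with
    at least ``min_cell_n`` values, on the raw and the log10 scale.  log10
    is selected when a majority of cells fail normality on the raw scale
    and more cells pass after logging than before.  Non-positive values
    force the identity scale with a warning, since the log is undefined.
    """
    vals = data[value_col].to_numpy(dtype=float)
    if np.any(vals <= 0):
        warnings.warn("non-positive values present: using identity transform")
        return TransformDecision("identity", pd.DataFrame(), "non-positive values")
    rows = []
    for cell, grp in data.groupby(list(cell_cols), sort=True):
        x = grp[value_col].to_numpy(dtype=float)
        if len(x) < min_cell_n:
            continue
        if np.ptp(x) == 0:
            continue  # Shapiro undefined on constant cells
        p_raw = sps.shapiro(x).pvalue
        p_log = sps.shapiro(np.log10(x)).pvalue
        rows.append({"cell": cell, "p_raw": p_raw, "p_log": p_log})
    cells = pd.DataFrame(rows)
    if cells.empty:
        return TransformDecision("identity", cells, "no testable cells")
    fail_raw = (cells["p_raw"] < alpha).mean()
    pass_raw = (cells["p_raw"] >= alpha).sum()
    pass_log = (cells["p_log"] >= alpha).sum()
    if fail_raw > 0.5 and pass_log > pass_raw:
        return TransformDecision(
            "log10", cells, f"{fail_raw:.0%} of cells non-normal raw; log10 passes more"
        )
    return TransformDecision("identity", cells, "raw scale acceptable")


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class PosthocComparison:
    level: str
    estimate: float
    se: float
    t: float
    df: float
    raw_p: float
    adjusted_p: float = np.nan
    band: str = ""


@dataclass
class MixedModelResult:
    biomarker: str
    transform_used: str
    method: str  # "mixedlm" | "ols_fallback"
    fixed_effect_tests: list  # (term, F, df_num, df_den, p)
    posthoc: list = field(default_factory=list)
    n_animals: int = 0
    n_obs: int = 0
    _fit: object = field(default=None, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)


def fit_lmm(
    data: pd.DataFrame,
    biomarker: str | None = None,
    transform: str = "auto",
    value_col: str = "value",
) -> MixedModelResult:
    """Fit ``value ~ group * level`` with a random intercept per animal.

    The model is fitted by REML.  Fixed-term F tests use Wald statistics
    with containment-style denominator degrees of freedom: the group main
    effect is tested against between-animal information
    (df = animals − groups), within-animal terms against residual df.
    Designs in which the random intercept is inestimable (one animal per
    group, or a boundary variance fit) fall back to an ordinary
    least-squares fit, reported as ``method='ols_fallback'``.

    Parameters
    ----------
    data : DataFrame with columns ``animal_id, group, level, value``
        (plus ``biomarker`` if ``biomarker`` filtering is requested).
    transform : {"auto", "identity", "log10"}
    """
    df = data.copy()
    if biomarker is not None and "biomarker" in df.columns:
        df = df[df["biomarker"] == biomarker]
    if df.empty:
        raise ValueError("no data to fit")
    if df["group"].nunique() < 2 or df["level"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 repeated levels")
    # drop unestimable group x level cells
    cell_n = df.groupby(["group", "level"], observed=True)["value"].size()
    empty_cells = [
        (g, l)
        for g in df["group"].unique()
        for l in df["level"].unique()
        if (g, l) not in cell_n.index
    ]
    if empty_cells:
        warnings.warn(f"empty design cells dropped from inference: {empty_cells}")

    if transform == "auto":
        decision = choose_transform(df, value_col=value_col)
        transform = decision.transform
    if transform == "log10":
        df = df.copy()
        df[value_col] = np.log10(df[value_col].to_numpy(dtype=float))
    formula = f"{value_col} ~ C(group) * C(level)"
    n_animals = df["animal_id"].nunique()
    n_groups = df["group"].nunique()

    fit, method = None, "mixedlm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["animal_id"])
            fit = model.fit(reml=True)
            if not np.isfinite(fit.fe_params).all() or n_animals <= n_groups:
                raise ValueError("degenerate mixed fit")
        except Exception:
            fit = smf.ols(formula, df).fit()
            method = "ols_fallback"

    fe_names = list(fit.fe_params.index) if method == "mixedlm" else list(fit.params.index)
    fe = np.asarray(fit.fe_params if method == "mixedlm" else fit.params, dtype=float)
    cov = np.asarray(fit.cov_params().loc[fe_names, fe_names], dtype=float)
    design_info = fit.model.data.design_info

    n_obs = len(df)
    resid_df = max(n_obs - len(fe_names) - (n_animals - 1), 1) if method == "mixedlm" else max(
        n_obs - len(fe_names), 1
    )
    tests = []
    for term in design_info.terms:
        name = term.name()
        if name == "Intercept":
            continue
        sl = design_info.term_name_slices[name]
        L = np.zeros((sl.stop - sl.start, len(fe_names)))
        for i, j in enumerate(range(sl.start, sl.stop)):
            L[i, j] = 1.0
        q = L.shape[0]
        Lb = L @ fe
        with np.errstate(invalid="ignore"):  # saturated fallback fits give NaN
            W = float(Lb @ np.linalg.solve(L @ cov @ L.T, Lb))
        Fstat = W / q
        ddf = (n_animals - n_groups) if name == "C(group)" else resid_df
        ddf = max(ddf, 1)
        p = float(sps.f.sf(Fstat, q, ddf))
        tests.append((name, Fstat, q, ddf, p))

    return MixedModelResult(
        biomarker=biomarker or "",
        transform_used=transform,
        method=method,
        fixed_effect_tests=tests,
        n_animals=n_animals,
        n_obs=n_obs,
        _fit=fit,
        _data=df,
    )


def group_effect_p(result: MixedModelResult) -> float:
    """p-value of the group main effect from a fitted model."""
    for name, _, _, _, p in result.fixed_effect_tests:
        if name == "C(group)":
            return p
    raise ValueError("no group term in fitted model")


def posthoc_within_levels(
    result: MixedModelResult,
    groups: tuple | None = None,
) -> list[PosthocComparison]:
    """Holm-Šídák-corrected group contrasts within each repeated level.

    For each level the marginal difference (group 2 − group 1) is formed as
    a linear contrast of the fixed effects and tested with a t statistic on
    between-animal degrees of freedom.  The family for correction is the
    set of levels of this one biomarker.  Levels missing one of the groups
    are skipped and recorded with a NaN estimate.
    """
    fit, df = result._fit, result._data
    if fit is None:
        raise ValueError("result does not carry a fitted model")
    design_info = fit.model.data.design_info
    fe_names = list((fit.fe_params if result.method == "mixedlm" else fit.params).index)
    fe = np.asarray(fit.fe_params if result.method == "mixedlm" else fit.params, dtype=float)
    cov = np.asarray(fit.cov_params().loc[fe_names, fe_names], dtype=float)
    all_groups = sorted(df["group"].unique())
    if groups is None:
        groups = (all_groups[0], all_groups[1])
    g1, g2 = groups
    ddf = max(df["animal_id"].nunique() - df["group"].nunique(), 1)

    comparisons, pvals = [], []
    for level in sorted(df["level"].unique()):
        present = set(df.loc[df["level"] == level, "group"])
        if not {g1, g2} <= present:
            comparisons.append(
                PosthocComparison(str(level), np.nan, np.nan, np.nan, ddf, np.nan)
            )
            continue
        new = pd.DataFrame({"group": [g1, g2], "level": [level, level]})
        (X,) = build_design_matrices([design_info], new)
        L = np.asarray(X)[1] - np.asarray(X)[0]
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se
        p = float(2 * sps.t.sf(abs(t), ddf))
        comparisons.append(PosthocComparison(str(level), est, se, t, ddf, p))
        pvals.append(p)
    adj = holm_sidak(pvals)
    it = iter(adj)
    for c in comparisons:
        if np.isfinite(c.raw_p):
            c.adjusted_p = float(next(it))
            c.band = significance_band(c.adjusted_p)
    result.posthoc = comparisons
    return comparisons


def posthoc_frame(comparisons: list[PosthocComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level": [c.level for c in comparisons],
            "estimate": [c.estimate for c in comparisons],
            "se": [c.se for c in comparisons],
            "raw_p": [c.raw_p for c in comparisons],
            "adjusted_p": [c.adjusted_p for c in comparisons],
            "band": [c.band for c in comparisons],
        }
    )


# ---------------------------------------------------------------------------
# Auxiliary tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples (n ≤ 25 each), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 observations")
    method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, r², two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
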