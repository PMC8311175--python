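"""Statistics layer: descriptives, agreement, trends and mixed models.

The analyses mirror a standard quantitative lameness workflow:

* descriptive summaries of the preexisting (straight-line) asymmetries,
  including a pooled intra-horse SD across repeated straight-line
  conditions;
* ordinary least-squares trend lines of straight-line vs. matching rein
  asymmetry (slope near 1 means the rein values track the straight line);
* Bland-Altman style limits of agreement (bias, SD, 2*SD band) between
  straight-line and matching average-rein values;
* random-intercept linear mixed models (horse as random factor; surface,
  speed and, where applicable, direction as fixed factors), fitted by REML,
  with Wald F tests on residual degrees of freedom, estimated marginal
  means over a balanced factor grid, and Bonferroni-adjusted pairwise
  contrasts.

All standard deviations use the n-1 denominator.  Significance is assessed
at alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .normalize import NormalizedDataset
from .synth import PARAMETERS

ALPHA = 0.05


# ---------------------------------------------------------------------------
# descriptives


@dataclass
class DescriptiveSummary:
    """Table-1 style summary of one parameter's straight-line values (mm)."""

    parameter: str
    mean: float
    sd: float
    mean_abs: float
    min: float
    max: float
    n: int
    n_left: int  # horses with positive (left-sided) straight-line mean
    n_right: int
    sd_defined: bool = True  # False when n == 1 (sd reported as 0)


def descriptives(straight: pd.DataFrame, parameter: str) -> DescriptiveSummary:
    """Descriptive statistics of one parameter across straight-line records.

    ``straight`` needs columns ``horse`` and ``parameter``; left/right
    counts classify each horse by the sign of its straight-line mean.
    """
    if parameter not in straight.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    values = straight[parameter].to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError("no records supplied")
    per_horse = straight.groupby("horse")[parameter].mean()
    sd_defined = len(values) > 1
    return DescriptiveSummary(
        parameter=parameter,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if sd_defined else 0.0,
        mean_abs=float(np.abs(values).mean()),
        min=float(values.min()),
        max=float(values.max()),
        n=len(values),
        n_left=int((per_horse > 0).sum()),
        n_right=int((per_horse < 0).sum()),
        sd_defined=sd_defined,
    )


def intra_horse_deviations(straight: pd.DataFrame, parameter: str) -> pd.Series:
    """Deviations of each straight-line value from its horse's mean.

    Only horses with at least two straight-line conditions contribute.
    """
    devs = []
    for horse, group in straight.groupby("horse"):
        v = group[parameter].to_numpy(dtype=float)
        if len(v) >= 2:
            devs.append(pd.Series(v - v.mean(), index=[horse] * len(v)))
    if not devs:
        raise ValueError(
            "no horse with at least two straight-line conditions: "
            "intra-horse SD undefined"
        )
    return pd.concat(devs)


def intra_horse_sd(straight: pd.DataFrame, parameter: str) -> float:
    """Pooled SD of within-horse straight-line deviations (mm).

    Deviations from each eligible horse's own straight-line mean are pooled
    across horses and summarised by a single SD (n-1 denominator), an
    indicator of intra-horse consistency of the preexisting asymmetry.
    """
    devs = intra_horse_deviations(straight, parameter)
    return float(devs.std(ddof=1))


def summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptives + intra-horse SD for all 11 parameters (straight rows)."""
    straight = records[records["direction"] == "straight"]
    rows = []
    for p in PARAMETERS:
        d = descriptives(straight, p)
        try:
            ih = intra_horse_sd(straight, p)
        except ValueError:
            ih = np.nan
        rows.append(
            {
                "parameter": p, "mean": d.mean, "sd": d.sd, "mean_abs": d.mean_abs,
                "min": d.min, "max": d.max, "n_left": d.n_left, "n_right": d.n_right,
                "intra_horse_sd": ih, "n": d.n,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# agreement and trends


@dataclass
class LoAResult:
    """Bland-Altman limits of agreement between two paired measurements."""

    bias: float  # mean of differences, mm
    sd: float  # SD of differences (n-1), mm
    band: float  # 2 * sd, mm
    n_pairs: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class TrendFit:
    """Ordinary least-squares line through paired asymmetry values."""

    slope: float
    intercept: float
    r2: float
    n: int


def limits_of_agreement(straight, average) -> LoAResult:
    """Limits of agreement between matched straight and average-rein values.

    Differences are taken as straight minus average per matched condition;
    the result reports their mean (bias), SD and the 2*SD band.
    """
    s = np.asarray(list(straight), dtype=float)
    a = np.asarray(list(average), dtype=float)
    if len(s) != len(a):
        raise ValueError("paired inputs must have equal length")
    if len(s) < 2:
        raise ValueError("need at least two matched pairs")
    d = s - a
    sd = float(d.std(ddof=1))
    return LoAResult(bias=float(d.mean()), sd=sd, band=2.0 * sd, n_pairs=len(d))


def linear_trend(x, y) -> TrendFit:
    """OLS trend of rein values (y) against straight-line values (x).

    A slope close to 1 indicates rein asymmetry similar to the straight
    line; below 1, reduced asymmetry on the rein.  ``r2`` is the squared
    Pearson correlation.  A constant-y input yields slope 0, r2 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: trend undefined")
    if np.ptp(y) == 0:
        return TrendFit(slope=0.0, intercept=float(y.mean()), r2=0.0, n=len(x))
    fit = scipy.stats.linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(x),
    )


def _matched_pairs(norm: NormalizedDataset, parameter: str, direction: str) -> pd.DataFrame:
    """Straight vs. ``direction`` values matched on horse, surface, speed."""
    rec = norm.records
    rec = rec[rec["parameter"] == parameter]
    keys = ["horse", "surface", "speed"]
    straight = rec[rec["direction"] == "straight"].set_index(keys)["value"]
    other = rec[rec["direction"] == direction].set_index(keys)["value"]
    pairs = pd.concat({"straight": straight, direction: other}, axis=1).dropna()
    return pairs


def agreement_table(norm: NormalizedDataset) -> pd.DataFrame:
    """Limits of agreement (straight vs. average rein) per parameter."""
    rows = []
    for p in PARAMETERS:
        pairs = _matched_pairs(norm, p, "average")
        loa = limits_of_agreement(pairs["straight"], pairs["average"])
        rows.append({"parameter": p, "mean": loa.bias, "sd": loa.sd,
                     "two_sd": loa.band, "n_pairs": loa.n_pairs})
    return pd.DataFrame(rows).set_index("parameter")


def trend_table(norm: NormalizedDataset) -> pd.DataFrame:
    """Slope/intercept/R² of straight vs. average/inside/outside, per parameter."""
    rows = []
    for p in PARAMETERS:
        for direction in ("average", "inside", "outside"):
            pairs = _matched_pairs(norm, p, direction)
            fit = linear_trend(pairs["straight"], pairs[direction])
            rows.append({"parameter": p, "direction": direction, "slope": fit.slope,
                         "intercept": fit.intercept, "r2": fit.r2, "n": fit.n})
    return pd.DataFrame(rows).set_index(["parameter", "direction"])


# ---------------------------------------------------------------------------
# mixed models


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, p * m)``.

    The unadjusted (Fisher's LSD) p-value is multiplied by the number of
    comparisons and capped at 1, so significance can be read against the
    conventional alpha of 5%.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return min(1.0, p * m)


@dataclass
class ModelResult:
    """A fitted random-intercept model for one response parameter."""

    response: str
    fixed: tuple[str, ...]
    p_values: dict[str, float]  # raw Wald-F p per fixed factor
    emms: dict[str, dict[str, float]]  # factor -> level -> EMM
    emm_diff: dict[str, float]  # |difference| between the two levels (2-level factors)
    var_horse: float  # random-intercept variance, mm^2
    var_resid: float  # residual variance, mm^2
    converged: bool
    singular: bool  # random-intercept variance estimated at (numerically) zero
    n_obs: int
    df_resid: int
    residuals: np.ndarray = field(repr=False)
    fe_params: np.ndarray = field(repr=False)
    cov_fe: np.ndarray = field(repr=False)
    _design_info: object = field(repr=False, default=None)
    _grid: pd.DataFrame | None = field(repr=False, default=None)
    _grid_X: np.ndarray | None = field(repr=False, default=None)


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str = "horse",
    reml: bool = True,
    drop_random_on_singular: bool = False,
) -> ModelResult:
    """Fit ``response = fixed main effects + horse intercept + residual``.

    Restricted maximum likelihood by default.  Fixed-factor p-values are
    Wald F tests with residual degrees of freedom (``n - k_fixed``);
    estimated marginal means are predictions averaged over a balanced grid
    of the other fixed factors.  Non-convergence and a singular (zero)
    random-intercept variance are flagged, never silent; with
    ``drop_random_on_singular`` a singular fit is refitted by OLS.

    Model residuals are exposed on the result for normality inspection
    (see :func:`residual_histogram`).
    """
    for col in (response, group, *fixed):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from model data")
    if data[group].nunique() < 2:
        raise ValueError("need at least two groups (horses)")
    for f in fixed:
        if data[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has fewer than two observed levels")
    data = data.reset_index(drop=True)
    formula = f"Q('{response}') ~ " + " + ".join(f"C({f})" for f in fixed)

    if np.ptp(data[response].to_numpy(dtype=float)) == 0:
        # degenerate constant response: REML cannot estimate two variances
        return _constant_response_result(data, response, fixed)

    model = smf.mixedlm(formula, data, groups=data[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    converged = bool(result.converged)
    var_horse = float(np.asarray(result.cov_re)[0, 0])
    var_resid = float(result.scale)
    singular = var_horse <= 1e-8 * max(var_resid, 1e-12)

    fe = np.asarray(result.fe_params, dtype=float)
    k = len(fe)
    cov_fe = np.asarray(result.cov_params(), dtype=float)[:k, :k]
    # marginal residuals computed directly (the fitted-value accessor needs
    # an invertible random-effect covariance, which a singular fit lacks)
    residuals = np.asarray(model.endog, dtype=float) - np.asarray(model.exog) @ fe

    if singular and drop_random_on_singular:
        ols = smf.ols(formula, data).fit()
        fe = np.asarray(ols.params, dtype=float)
        cov_fe = np.asarray(ols.cov_params(), dtype=float)
        residuals = np.asarray(ols.resid, dtype=float)
        var_horse = 0.0
        var_resid = float(ols.mse_resid)
        converged = True

    design_info = model.data.design_info
    n = len(data)
    df_resid = n - k
    p_values = {}
    for f in fixed:
        sl = design_info.term_name_slices[f"C({f})"]
        b = fe[sl]
        V = cov_fe[sl, sl]
        q = len(b)
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            chi2 = np.nan
        p_values[f] = float(scipy.stats.f.sf(chi2 / q, q, df_resid))

    grid = _balanced_grid(data, fixed)
    grid_X = np.asarray(build_design_matrices([design_info], grid)[0])
    pred = grid_X @ fe
    emms: dict[str, dict[str, float]] = {}
    emm_diff: dict[str, float] = {}
    for f in fixed:
        levels = sorted(data[f].unique())
        emms[f] = {lv: float(pred[grid[f] == lv].mean()) for lv in levels}
        if len(levels) == 2:
            emm_diff[f] = abs(emms[f][levels[0]] - emms[f][levels[1]])

    return ModelResult(
        response=response,
        fixed=tuple(fixed),
        p_values=p_values,
        emms=emms,
        emm_diff=emm_diff,
        var_horse=var_horse,
        var_resid=var_resid,
        converged=converged,
        singular=singular,
        n_obs=n,
        df_resid=df_resid,
        residuals=residuals,
        fe_params=fe,
        cov_fe=cov_fe,
        _design_info=design_info,
        _grid=grid,
        _grid_X=grid_X,
    )


def _balanced_grid(data: pd.DataFrame, fixed: Sequence[str]) -> pd.DataFrame:
    levels = [sorted(data[f].unique()) for f in fixed]
    grid = pd.MultiIndex.from_product(levels, names=list(fixed)).to_frame(index=False)
    return grid


def _constant_response_result(
    data: pd.DataFrame, response: str, fixed: Sequence[str]
) -> ModelResult:
    value = float(data[response].iloc[0])
    emms = {f: {lv: value for lv in sorted(data[f].unique())} for f in fixed}
    emm_diff = {f: 0.0 for f in fixed if data[f].nunique() == 2}
    return ModelResult(
        response=response,
        fixed=tuple(fixed),
        p_values={f: 1.0 for f in fixed},
        emms=emms,
        emm_diff=emm_diff,
        var_horse=0.0,
        var_resid=0.0,
        converged=True,
        singular=True,
        n_obs=len(data),
        df_resid=len(data) - 1,
        residuals=np.zeros(len(data)),
        fe_params=np.array([value]),
        cov_fe=np.zeros((1, 1)),
    )


def estimated_marginal_means(result: ModelResult, factor: str) -> dict[str, float]:
    """EMMs of one fixed factor: predictions over a balanced grid.

    Each level's EMM is the model prediction for that level averaged over a
    fully crossed (balanced) grid of the remaining fixed factors, so
    imbalance in the observed design does not leak into the level means.
    """
    if factor not in result.emms:
        raise ValueError(
            f"unknown factor {factor!r}; model factors: {', '.join(result.fixed)}"
        )
    return dict(result.emms[factor])


def pairwise_comparisons(result: ModelResult, factor: str) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise EMM contrasts between factor levels.

    Intended for the three-level movement-direction factor of the
    stride-time model; requires at least three levels.  The adjustment
    multiplies each contrast's Wald-t p-value by the number of pairs.
    """
    if factor not in result.emms:
        raise ValueError(f"unknown factor {factor!r}")
    levels = sorted(result.emms[factor].keys())
    if len(levels) < 3:
        raise ValueError("pairwise comparisons need a factor with at least three levels")
    if result._grid is None or result._grid_X is None:
        raise ValueError("model result lacks a prediction grid")
    grid, X = result._grid, result._grid_X
    npairs = len(levels) * (len(levels) - 1) // 2
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            la = X[(grid[factor] == a).to_numpy()].mean(axis=0)
            lb = X[(grid[factor] == b).to_numpy()].mean(axis=0)
            contrast = la - lb
            est = float(contrast @ result.fe_params)
            se = float(np.sqrt(contrast @ result.cov_fe @ contrast))
            if se == 0:
                t, p = 0.0, 1.0
            else:
                t = est / se
                p = float(2 * scipy.stats.t.sf(abs(t), result.df_resid))
            rows.append({
                "level_a": a, "level_b": b, "estimate": est, "se": se,
                "t": t, "p_raw": p, "p_adjusted": bonferroni_adjust(p, npairs),
            })
    return pd.DataFrame(rows)


# alias matching the domain vocabulary (contrasts between movement directions)
pairwise_direction_comparisons = pairwise_comparisons


def residual_histogram(result: ModelResult, path) -> None:
    """Save a residual histogram for visual normality inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(result.residuals, bins=30, color="steelblue", edgecolor="white")
    ax.set_xlabel("residual (mm)")
    ax.set_ylabel("count")
    ax.set_title(f"{result.response} model residuals")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# study-level analyses


def stride_time_model(records: pd.DataFrame) -> tuple[ModelResult, pd.DataFrame]:
    """Mixed model of stride time with surface, speed and direction.

    Fitted on the raw (left/right/straight) condition table; the pairwise
    direction contrasts check whether stride time — the proxy for speed —
    differs between reins and between straight line and lunge.
    """
    result = fit_mixed_model(records, "stride_time", ("surface", "speed", "direction"))
    pairs = pairwise_comparisons(result, "direction")
    return result, pairs


def straight_vs_average_models(norm: NormalizedDataset) -> pd.DataFrame:
    """Per-parameter mixed models on straight-line and average-rein data.

    Fixed factors: surface, speed, direction (straight vs. average rein);
    random horse intercept.  One row per parameter with p-values, EMMs and
    |EMM difference| per factor.
    """
    rows = []
    for p in PARAMETERS:
        rec = norm.records
        data = rec[(rec["parameter"] == p) & rec["direction"].isin(["straight", "average"])]
        data = data.rename(columns={"value": p})
        mr = fit_mixed_model(data, p, ("surface", "speed", "direction"))
        row = {"parameter": p, "converged": mr.converged,
               "var_horse": mr.var_horse, "var_resid": mr.var_resid}
        for f in ("surface", "speed", "direction"):
            row[f"p_{f}"] = mr.p_values[f]
            for lv, v in mr.emms[f].items():
                row[f"emm_{f}_{lv}"] = v
            row[f"diff_{f}"] = mr.emm_diff.get(f, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def individual_rein_models(norm: NormalizedDataset) -> pd.DataFrame:
    """Per-parameter, per-rein (inside/outside) surface x speed mixed models."""
    rows = []
    for p in PARAMETERS:
        for rein in ("inside", "outside"):
            rec = norm.records
            data = rec[(rec["parameter"] == p) & (rec["direction"] == rein)]
            data = data.rename(columns={"value": p})
            mr = fit_mixed_model(data, p, ("surface", "speed"))
            row = {"parameter": p, "rein": rein, "converged": mr.converged,
                   "var_horse": mr.var_horse, "var_resid": mr.var_resid}
            for f in ("surface", "speed"):
                row[f"p_{f}"] = mr.p_values[f]
                for lv, v in mr.emms[f].items():
                    row[f"emm_{f}_{lv}"] = v
                row[f"diff_{f}"] = mr.emm_diff.get(f, np.nan)
            rows.append(row)
    return pd.DataFrame(rows).set_index(["parameter", "rein"])


def count_speed_significant(
    individual: pd.DataFrame, average: pd.DataFrame, alpha: float = ALPHA
) -> tuple[int, int]:
    """(n individual-rein, n average-rein) parameters with a speed effect.

    A parameter counts as speed-affected on the individual reins if either
    its inside- or outside-rein model shows p < alpha for speed; on the
    average rein if the straight/average model does.
    """
    indiv = (
        individual.reset_index().groupby("parameter")["p_speed"].min() < alpha
    ).sum()
    avg = (average["p_speed"] < alpha).sum()
    return int(indiv), int(avg)


@dataclass
class StudyAnalysis:
    """All result tables of one study analysis run."""

    table1: pd.DataFrame  # descriptives + intra-horse SD
    stride_time: ModelResult
    stride_time_pairwise: pd.DataFrame
    trends: pd.DataFrame  # slope/intercept/R2 per parameter x direction
    agreement: pd.DataFrame  # limits of agreement per parameter
    straight_vs_average: pd.DataFrame
    individual_rein: pd.DataFrame
    norm: NormalizedDataset


def run_full_analysis(records: pd.DataFrame, norm: NormalizedDataset | None = None) -> StudyAnalysis:
    """The complete statistics chain on a wide condition table."""
    from .normalize import normalize_dataset

    if norm is None:
        norm = normalize_dataset(records)
    st_model, st_pairs = stride_time_model(records)
    return StudyAnalysis(
        table1=summary_table(records),
        stride_time=st_model,
        stride_time_pairwise=st_pairs,
        trends=trend_table(norm),
        agreement=agreement_table(norm),
        straight_vs_average=straight_vs_average_models(norm),
        individual_rein=individual_rein_models(norm),
        norm=norm,
    )
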