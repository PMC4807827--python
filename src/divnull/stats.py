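"""Seasonal-change inference.

Covers the change statistic ``-1*(1 - dry/wet)`` (equivalently
``dry/wet - 1``; negative = loss), paired observed-vs-null t comparisons,
functional/phylogenetic redundancy regressions (``response ~ SR`` vs
``response ~ SR + SR^2`` chosen by AIC, quadratic term deleted first), and a
Moran's I spatial-autocorrelation check, all aggregated into a
:class:`SeasonalReport`.

Note on test choice: paired comparisons use the classical one-sample t on
per-site differences (df = n - 1). A Welch correction is undefined for a
paired design, so the Welch variant here (:func:`welch_test`) applies only to
unpaired two-sample comparisons and is not used by the default report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InputError
from .io import SiteCoordinates
from .nullmodel import NullEvaluation

STATISTICS = ("SR", "FD", "PD")


def relative_change(wet: float, dry: float) -> float:
    """Relative seasonal change ``-1*(1 - dry/wet)``.

    0 when the two seasons agree, -1 when everything is lost, positive when
    the dry season exceeds the wet.
    """
    if wet <= 0:
        raise InputError(f"wet-season value must be positive, got {wet}")
    if dry < 0:
        raise InputError(f"dry-season value must be non-negative, got {dry}")
    return -1.0 * (1.0 - dry / wet)


@dataclass(frozen=True)
class PairedTestReport:
    name: str
    n: int
    mean_difference: float
    t: float
    df: int
    p: float


def paired_test(
    observed: Sequence[float], expected: Sequence[float], name: str = "paired t"
) -> PairedTestReport:
    """Two-sided paired t-test: one-sample t on per-site differences vs 0."""
    a = np.asarray(observed, dtype=float)
    b = np.asarray(expected, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired test needs two equal-length 1-d sequences")
    d = a - b
    ok = np.isfinite(d)
    d = d[ok]
    n = d.size
    if n < 2:
        raise InputError("paired test needs at least 2 finite pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise InputError("zero variance of differences; t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTestReport(name, n, float(d.mean()), float(t), n - 1, float(p))


def welch_test(
    sample_a: Sequence[float], sample_b: Sequence[float], name: str = "Welch t"
) -> PairedTestReport:
    """Two-sided Welch t-test for two independent samples (unpaired variant)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("Welch test needs at least 2 values per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    df = float(res.df)
    return PairedTestReport(
        name, a.size + b.size, float(a.mean() - b.mean()), float(res.statistic), df, float(res.pvalue)
    )


@dataclass(frozen=True)
class RedundancyReport:
    """AICc-selected FD~SR (or PD~SR) polynomial regression.

    ``redundancy`` is flagged when the quadratic model wins the model
    comparison AND its curvature is negative: added species then contribute
    progressively less new branch length, the saturating signature of
    functional (or phylogenetic) redundancy.
    """

    label: str
    n: int
    linear_coef: float
    quadratic_coef: float | None
    aic_full: float
    aic_reduced: float
    selected: str  # "quadratic" | "linear"
    r_squared: float
    p_linear: float
    p_quadratic: float | None
    max_leverage: float
    max_abs_studentized_resid: float

    @property
    def redundancy(self) -> bool:
        return self.selected == "quadratic" and (self.quadratic_coef or 0) < 0


def _aic(result) -> float:
    """Small-sample corrected Gaussian AIC (AICc), sigma^2 counted as a parameter.

    With a dozen sites, plain AIC retains a spurious quadratic term in roughly
    a fifth of pure-noise fits (the asymptotic P(chi2_1 > 2) ~ 0.16 problem);
    the AICc penalty brings that down to a few percent, which is what a
    model-selection step on 12 assemblages needs to be trustworthy.
    """
    k = result.df_model + 2  # coefficients incl. intercept, plus sigma^2
    n = result.nobs
    aic = -2.0 * result.llf + 2.0 * k
    if n - k - 1 <= 0:
        return float("inf")  # AICc undefined; model unsupportable at this n
    return float(aic + 2.0 * k * (k + 1) / (n - k - 1))


def redundancy_regression(
    sr: Sequence[float],
    response: Sequence[float],
    label: str = "FD",
    evidence_margin: float = 2.0,
) -> RedundancyReport:
    """Fit ``response ~ SR + SR^2`` and ``response ~ SR``; AICc decides.

    Stepwise deletion starts from the quadratic term: it is retained only when
    the full model improves AICc by more than ``evidence_margin`` (models
    within ~2 units have substantial support either way, so the simpler one
    wins ties and near-ties).
    """
    x = np.asarray(sr, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size:
        raise InputError("sr and response must have equal length")
    if x.size < 4:
        raise InputError("redundancy regression needs at least 4 sites")
    if np.unique(x).size < 2:
        raise InputError("SR is constant; regression undefined")
    if np.unique(x).size < 3:
        raise InputError(
            "fewer than 3 distinct SR values; quadratic fit is rank deficient"
        )
    X_full = sm.add_constant(np.column_stack([x, x**2]))
    X_red = sm.add_constant(x)
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    aic_full, aic_red = _aic(full), _aic(red)
    use_full = aic_full < aic_red - evidence_margin
    sel = full if use_full else red
    infl = sel.get_influence()
    return RedundancyReport(
        label=label,
        n=int(x.size),
        linear_coef=float(sel.params[1]),
        quadratic_coef=float(full.params[2]) if use_full else None,
        aic_full=aic_full,
        aic_reduced=aic_red,
        selected="quadratic" if use_full else "linear",
        r_squared=float(sel.rsquared),
        p_linear=float(sel.pvalues[1]),
        p_quadratic=float(full.pvalues[2]) if use_full else None,
        max_leverage=float(np.max(infl.hat_matrix_diag)),
        max_abs_studentized_resid=float(
            np.max(np.abs(infl.resid_studentized_internal))
        ),
    )


@dataclass(frozen=True)
class MoranReport:
    variable: str
    n: int
    observed: float
    expected: float
    sd: float
    p: float


def morans_i(
    values: Sequence[float],
    coords: SiteCoordinates | np.ndarray,
    sites: Sequence | None = None,
    row_standardise: bool = False,
    name: str = "I",
) -> MoranReport:
    """Moran's I with inverse-Euclidean-distance weights.

    Expectation, variance and two-sided p-value follow the randomisation
    assumption (normal approximation, kurtosis-corrected variance). Weights
    are 1/d with a zero diagonal; ``row_standardise=True`` divides each row by
    its sum (the convention of the classical R implementation in ape).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 3:
        raise InputError("Moran's I needs at least 3 sites")
    if isinstance(coords, SiteCoordinates):
        xy = coords.xy(list(sites) if sites is not None else list(coords.sites))
    else:
        xy = np.asarray(coords, dtype=float)
    if xy.shape != (n, 2):
        raise InputError("coordinates must be (n, 2) and match the values")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        raise InputError("coincident sites; inverse-distance weights degenerate")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    if row_standardise:
        w = w / w.sum(axis=1, keepdims=True)
    z = y - y.mean()
    ss = (z**2).sum()
    if ss == 0:
        raise InputError("constant values; Moran's I undefined")
    s0 = w.sum()
    obs = (n / s0) * (z @ w @ z) / ss
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = ((z**4).sum() / n) / ((ss / n) ** 2)
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - 1.0 / (n - 1) ** 2
    sd = float(np.sqrt(var))
    p = float(2.0 * sps.norm.sf(abs((obs - e_i) / sd)))
    return MoranReport(name, n, float(obs), float(e_i), sd, min(p, 1.0))


@dataclass
class SeasonalReport:
    """Everything the seasonal analysis produces, as tidy tables."""

    per_site: pd.DataFrame
    global_tests: pd.DataFrame
    regressions: pd.DataFrame
    morans: pd.DataFrame | None = None
    null_summary: pd.DataFrame | None = None

    def to_csvs(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("per_site_diversity", self.per_site),
            ("global_tests", self.global_tests),
            ("regressions", self.regressions),
            ("morans_i", self.morans),
            ("null_summary", self.null_summary),
        ):
            if frame is None:
                continue
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False, float_format="%.10g")
            paths[name] = path
        return paths


def _test_row(report: PairedTestReport) -> dict:
    return {
        "test": report.name,
        "n": report.n,
        "mean_difference": report.mean_difference,
        "t": report.t,
        "df": report.df,
        "p": report.p,
    }


def season_summary(
    observed: pd.DataFrame,
    null_eval: NullEvaluation,
    coords: SiteCoordinates | None = None,
    row_standardise: bool = False,
) -> SeasonalReport:
    """Aggregate observed and null results into the full seasonal report.

    ``observed`` is the frame from
    :func:`divnull.nullmodel.observed_diversity`; ``null_eval`` the evaluated
    ensemble over the same sites. Observed-vs-null pairing uses the per-site
    null MEAN; the per-site table also carries the null median and the
    standardised effect size (observed - null mean)/null SD, plus the
    observed value's quantile within the null distribution.
    """
    sites = list(null_eval.sites)
    obs = observed.set_index(["site", "season"])
    stats_present = [s for s in STATISTICS if s in observed.columns]

    # ---- per-site table --------------------------------------------------
    rows = []
    obs_change: dict = {s: [] for s in stats_present}
    null_change_mean: dict = {s: [] for s in stats_present}
    obs_val: dict = {(s, se): [] for s in stats_present for se in ("wet", "dry")}
    null_val_mean: dict = {(s, se): [] for s in stats_present for se in ("wet", "dry")}
    for site in sites:
        for season in ("wet", "dry"):
            row = {"site": site, "season": season}
            for stat in stats_present:
                v = float(obs.loc[(site, season), stat])
                arr = null_eval.values[site][season].get(stat)
                row[stat] = v
                obs_val[(stat, season)].append(v)
                if arr is None:
                    continue
                finite = arr[np.isfinite(arr)]
                m, sd = float(finite.mean()), float(finite.std(ddof=1))
                row[f"{stat}_null_mean"] = m
                row[f"{stat}_null_sd"] = sd
                row[f"{stat}_null_median"] = float(np.median(finite))
                row[f"{stat}_ses"] = (v - m) / sd if sd > 0 else np.nan
                row[f"{stat}_null_quantile"] = float((finite < v).mean())
                null_val_mean[(stat, season)].append(m)
            rows.append(row)
        # change rows
        row = {"site": site, "season": "change"}
        for stat in stats_present:
            wet = float(obs.loc[(site, "wet"), stat])
            dry = float(obs.loc[(site, "dry"), stat])
            change = relative_change(wet, dry) if wet > 0 else np.nan
            row[stat] = change
            obs_change[stat].append(change)
            arr = null_eval.change[site].get(stat)
            if arr is not None:
                finite = arr[np.isfinite(arr)]
                m = float(finite.mean()) if finite.size else np.nan
                sd = float(finite.std(ddof=1)) if finite.size > 1 else np.nan
                row[f"{stat}_null_mean"] = m
                row[f"{stat}_null_sd"] = sd
                row[f"{stat}_null_median"] = (
                    float(np.median(finite)) if finite.size else np.nan
                )
                row[f"{stat}_ses"] = (change - m) / sd if sd and sd > 0 else np.nan
                null_change_mean[stat].append(m)
        rows.append(row)
    per_site = pd.DataFrame(rows)

    # ---- global paired tests --------------------------------------------
    tests = []
    tests.append(
        _test_row(
            paired_test(
                obs_val[("SR", "wet")], obs_val[("SR", "dry")], "SR wet vs dry"
            )
        )
    )
    for stat in stats_present:
        if stat == "SR":
            continue  # null SR == observed SR by construction: nothing to test
        tests.append(
            _test_row(
                paired_test(
                    obs_change[stat],
                    null_change_mean[stat],
                    f"{stat} change: observed vs null",
                )
            )
        )
        for season in ("wet", "dry"):
            tests.append(
                _test_row(
                    paired_test(
                        obs_val[(stat, season)],
                        null_val_mean[(stat, season)],
                        f"{stat} {season}: observed vs null",
                    )
                )
            )
    global_tests = pd.DataFrame(tests)

    # ---- redundancy regressions -----------------------------------------
    reg_rows = []
    for season in ("wet", "dry"):
        sr = obs_val[("SR", season)]
        for stat in stats_present:
            if stat == "SR":
                continue
            for source, ys in (
                ("observed", obs_val[(stat, season)]),
                ("null_mean", null_val_mean[(stat, season)]),
            ):
                rep = redundancy_regression(
                    sr, ys, label=f"{stat} {source} ~ SR ({season})"
                )
                reg_rows.append(
                    {
                        "season": season,
                        "response": f"{stat}_{source}",
                        **{
                            k: getattr(rep, k)
                            for k in (
                                "n",
                                "linear_coef",
                                "quadratic_coef",
                                "aic_full",
                                "aic_reduced",
                                "selected",
                                "r_squared",
                                "p_linear",
                                "p_quadratic",
                                "max_leverage",
                                "max_abs_studentized_resid",
                            )
                        },
                        "redundancy": rep.redundancy,
                    }
                )
    regressions = pd.DataFrame(reg_rows)

    # ---- Moran's I -------------------------------------------------------
    morans = None
    if coords is not None:
        m_rows = []
        for stat in stats_present:
            series = {
                f"{stat} wet": obs_val[(stat, "wet")],
                f"{stat} dry": obs_val[(stat, "dry")],
                f"{stat} change": obs_change[stat],
            }
            for label, vals in series.items():
                try:
                    rep = morans_i(
                        vals,
                        coords,
                        sites=sites,
                        row_standardise=row_standardise,
                        name=label,
                    )
                    m_rows.append(
                        {
                            "variable": label,
                            "n": rep.n,
                            "I": rep.observed,
                            "expected": rep.expected,
                            "sd": rep.sd,
                            "p": rep.p,
                        }
                    )
                except InputError as exc:
                    m_rows.append(
                        {
                            "variable": label,
                            "n": len(vals),
                            "I": np.nan,
                            "expected": np.nan,
                            "sd": np.nan,
                            "p": np.nan,
                            "note": str(exc),
                        }
                    )
        morans = pd.DataFrame(m_rows)

    return SeasonalReport(
        per_site=per_site,
        global_tests=global_tests,
        regressions=regressions,
        morans=morans,
        null_summary=null_eval.summary(),
    )
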