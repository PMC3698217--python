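"""Two-window moderated-F differential testing of transient vs sustained arms.

Per gene the response is the log2 treated/reference ratio of each array
against its time-matched untreated reference.  Two separate linear models
are fitted per gene — an early window (0-4 h) and the main window (6-14 h) —
with one coefficient per (arm x time point) cell.  The tested contrast is
transient minus sustained at each time point shared by both arms; overall
significance across time is assessed with an empirical-Bayes moderated
F-test: gene-wise residual variances are shrunk toward a scaled
inverse-chi-square prior fitted across genes, and the F statistic uses the
posterior variance with augmented (d0 + d) denominator degrees of freedom.
Genes with Benjamini-Hochberg FDR < alpha in either window are called
significant; direction is the sign of the mean main-window contrast.

The module is organised as a model object fitted to data:

>>> model = TimecourseDE(matrix, sheet)      # doctest: +SKIP
>>> results = model.fit(alpha=0.05)          # doctest: +SKIP
>>> results.summary().head()                 # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import pair_conditions, validate_matrix, validate_sheet

WINDOWS: dict[str, tuple[float, float]] = {"early": (0.0, 4.0), "main": (6.0, 14.0)}

MIN_PRIOR_GENES = 10


class WindowError(ValueError):
    """Raised when a time window cannot support the linear model."""


# ---------------------------------------------------------------------------
# per-window ordinary least squares


@dataclass
class WindowModelFit:
    """OLS fits of one time window, all genes at once.

    beta: genes x shared-time contrast estimates (transient - sustained);
    s2: residual variance per gene; df: residual degrees of freedom (scalar,
    shared design); cov_unscaled: contrast covariance / sigma^2.
    """

    window: str
    times: list[float]
    beta: pd.DataFrame
    s2: pd.Series
    df: int
    cov_unscaled: np.ndarray


def fit_window_model(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    window: str,
    arms: tuple[str, str] = ("transient", "sustained"),
    windows: dict[str, tuple[float, float]] | None = None,
) -> WindowModelFit:
    """Fit the cell-means model for one window and form the arm contrast."""
    validate_matrix(matrix)
    validate_sheet(sheet, matrix)
    windows = windows if windows is not None else WINDOWS
    if window not in windows:
        raise WindowError(f"unknown window {window!r}; choose from {list(windows)}")
    lo, hi = windows[window]

    obs_cols, cells = [], []
    for arm in arms:
        pairs = pair_conditions(sheet, arm)
        times = sheet.set_index("sample_id")["time_h"]
        for treated, ref in pairs.items():
            t = round(float(times[treated]), 3)
            if lo <= t <= hi:
                obs_cols.append((treated, ref))
                cells.append((arm, t))
    if not obs_cols:
        raise WindowError(f"window {window!r}: no treated samples in [{lo}, {hi}] h")

    cell_levels = sorted(set(cells))
    arm_times = {arm: sorted({t for a, t in cell_levels if a == arm}) for arm in arms}
    shared = sorted(set(arm_times[arms[0]]) & set(arm_times[arms[1]]))
    if len(shared) < 2:
        raise WindowError(
            f"window {window!r}: needs >= 2 time points shared by both arms, "
            f"got {shared}"
        )

    # response: log2 ratio per observation; design: one column per cell
    y = np.column_stack([
        matrix[t].to_numpy() - matrix[r].to_numpy() for t, r in obs_cols
    ])  # genes x obs
    n_obs, n_par = len(obs_cols), len(cell_levels)
    x = np.zeros((n_obs, n_par))
    for i, cell in enumerate(cells):
        x[i, cell_levels.index(cell)] = 1.0
    df = n_obs - n_par
    if df < 1:
        raise WindowError(
            f"window {window!r}: zero residual degrees of freedom "
            f"({n_obs} observations, {n_par} parameters)"
        )

    xtx = x.T @ x
    xtx_inv = linalg.inv(xtx)
    coef = y @ x @ xtx_inv.T  # genes x cells
    resid = y - coef @ x.T
    s2 = (resid ** 2).sum(axis=1) / df

    contrast = np.zeros((len(shared), n_par))
    for k, t in enumerate(shared):
        contrast[k, cell_levels.index((arms[0], t))] = 1.0
        contrast[k, cell_levels.index((arms[1], t))] = -1.0
    beta = coef @ contrast.T
    cov_unscaled = contrast @ xtx_inv @ contrast.T

    return WindowModelFit(
        window=window,
        times=shared,
        beta=pd.DataFrame(beta, index=matrix.index, columns=shared),
        s2=pd.Series(s2, index=matrix.index, name="s2"),
        df=df,
        cov_unscaled=cov_unscaled,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2, df) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior (d0, s0^2) to sample variances.

    Moment-matches the log-variances: with s^2 | sigma^2 ~ sigma^2 chi^2_d/d
    and sigma^2 from the prior, e = log(s^2) - digamma(d/2) + log(d/2) has
    mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(d/2); the trigamma is
    inverted by Newton iteration.  When the empirical spread of log s^2 is
    at or below its expected sampling value, d0 is flagged infinite and
    s0^2 is the arithmetic mean of the sample variances.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (df_arr >= 1) & np.isfinite(s2)
    if (s2[ok] == 0).all():
        raise ValueError("all residual variances are zero; degenerate prior")
    keep = ok & (s2 > 0)
    if keep.sum() < MIN_PRIOR_GENES:
        raise ValueError(
            f"prior estimation needs >= {MIN_PRIOR_GENES} genes with d >= 1 "
            f"and s^2 > 0, got {int(keep.sum())}"
        )
    s2, d = s2[keep], df_arr[keep]
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if e_var <= 0:
        # no dispersion beyond sampling: all true variances equal s0^2, and
        # the arithmetic mean of s^2 is its unbiased estimate
        return np.inf, float(s2.mean())
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_2 = np.exp(e_mean + digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_2)


def moderated_f(fit: WindowModelFit, prior: tuple[float, float]) -> pd.DataFrame:
    """Moderated F statistics, p-values and BH-FDR for one window fit."""
    d0, s0_2 = prior
    d = fit.df
    s2 = fit.s2.to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    if (s2_post <= 0).any():
        raise ValueError("non-positive posterior variance")
    k = fit.beta.shape[1]
    ci = linalg.inv(fit.cov_unscaled)
    b = fit.beta.to_numpy()
    quad = np.einsum("gi,ij,gj->g", b, ci, b)
    f = quad / k / s2_post
    if np.isinf(df_total):
        p = stats.chi2.sf(k * f, k)
    else:
        p = stats.f.sf(f, k, df_total)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "s2": s2, "s2_post": s2_post, "df_resid": d, "df_prior": d0,
            "s0_2": s0_2, "F": f, "p": p, "fdr": fdr,
        },
        index=fit.beta.index,
    )


def _exact_data_stats(fit: WindowModelFit) -> pd.DataFrame:
    """Noise-free limit: all residual variances vanish, so any contrast
    beyond numerical tolerance is unambiguously significant (p=0) and an
    exactly null contrast is not (p=1)."""
    k = fit.beta.shape[1]
    ci = linalg.inv(fit.cov_unscaled)
    b = fit.beta.to_numpy()
    quad = np.einsum("gi,ij,gj->g", b, ci, b)
    nonzero = quad / k > 1e-10
    p = np.where(nonzero, 0.0, 1.0)
    return pd.DataFrame(
        {
            "s2": fit.s2.to_numpy(), "s2_post": 0.0, "df_resid": fit.df,
            "df_prior": np.nan, "s0_2": 0.0,
            "F": np.where(nonzero, np.inf, 0.0), "p": p, "fdr": p,
        },
        index=fit.beta.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-stable)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-d array")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results objects


class TimecourseDE:
    """Transient-vs-sustained differential expression over a time course.

    Parameters
    ----------
    matrix : DataFrame
        Normalized log2 expression, probes x samples.
    sheet : DataFrame
        Sample sheet with time-matched untreated references for both arms.
    windows : mapping, optional
        {name: (lo_h, hi_h)}; defaults to the early (0-4 h) and main
        (6-14 h) windows.
    """

    def __init__(self, matrix: pd.DataFrame, sheet: pd.DataFrame,
                 windows: dict[str, tuple[float, float]] | None = None,
                 arms: tuple[str, str] = ("transient", "sustained")):
        self.matrix = validate_matrix(matrix)
        self.sheet = validate_sheet(sheet, matrix)
        self.windows = dict(windows) if windows is not None else dict(WINDOWS)
        self.arms = arms

    def fit(self, alpha: float = 0.05) -> "TimecourseDEResults":
        fits, stats_tables = {}, {}
        for name in self.windows:
            fit = fit_window_model(self.matrix, self.sheet, name, self.arms,
                                   windows=self.windows)
            fits[name] = fit
            if fit.s2.max() <= 1e-12:
                stats_tables[name] = _exact_data_stats(fit)
            else:
                prior = estimate_prior(fit.s2, fit.df)
                stats_tables[name] = moderated_f(fit, prior)
        return TimecourseDEResults(self, fits, stats_tables, alpha)


@dataclass
class TimecourseDEResults:
    """Fitted per-window statistics plus the combined significance call."""

    model: TimecourseDE
    fits: dict[str, WindowModelFit]
    stats: dict[str, pd.DataFrame]
    alpha: float
    _table: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        genes = self.model.matrix.index
        sig_any = pd.Series(False, index=genes)
        cols = {}
        for name, tab in self.stats.items():
            sig = tab["fdr"] < self.alpha
            sig_any |= sig
            cols[f"F_{name}"] = tab["F"]
            cols[f"p_{name}"] = tab["p"]
            cols[f"fdr_{name}"] = tab["fdr"]
            cols[f"significant_{name}"] = sig
        main = "main" if "main" in self.fits else list(self.fits)[-1]
        mean_contrast = self.fits[main].beta.mean(axis=1)
        direction = np.where(mean_contrast < 0, "lower_in_transient",
                             "higher_in_transient")
        self._table = pd.DataFrame(cols)
        self._table["significant"] = sig_any
        self._table["direction"] = direction
        self._table["mean_contrast_main"] = mean_contrast

    @property
    def significant(self) -> pd.Series:
        return self._table["significant"]

    @property
    def direction(self) -> pd.Series:
        return self._table["direction"]

    def summary(self) -> pd.DataFrame:
        """Per-gene table: window F/p/FDR, union call and direction."""
        return self._table.copy()

    def to_frame(self) -> pd.DataFrame:
        """Full output table including contrast estimates per time point."""
        parts = [self._table]
        for name, fit in self.fits.items():
            b = fit.beta.copy()
            b.columns = [f"beta_{name}_{t:g}h" for t in b.columns]
            parts.append(b)
        return pd.concat(parts, axis=1)


def call_differential(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    windows: dict[str, tuple[float, float]] | None = None,
) -> TimecourseDEResults:
    """Convenience wrapper: fit both windows and return the results object."""
    return TimecourseDE(matrix, sheet, windows=windows).fit(alpha=alpha)
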