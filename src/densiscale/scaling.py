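"""Single and segmented power-law fits of indicator density vs population density.

On log10 scales the single law is a straight line,
``log y = log y0 + beta log d``, and the segmented law is a continuous
two-slope (hinge) line with a critical density d*:

    log y = log y0 + beta_L log d                      (d <  d*)
    log y = log y1 + beta_H log d                      (d >= d*)
    log y1 = log y0 + (beta_L - beta_H) log d*         (continuity)

The hinge basis {1, x, max(0, x - psi)} with x = log10 d and psi = log10 d*
makes the continuity constraint automatic; the break location is estimated
by profiling the OLS residual sum of squares over candidate psi on interior
quantiles and refining the best grid cell with a golden-section search.

The significance of a change of slope is assessed with Davies' (1987) upper
bound for a test whose nuisance parameter (the break) is absent under the
null, and the segmented model is accepted only when that test rejects at the
99% level *and* BIC favours it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_io import DensityMatrix

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few finite points for the requested fit."""


class DegenerateDesignError(ValueError):
    """The design matrix is rank-deficient (e.g. constant log d)."""


class ConsistencyError(ValueError):
    """Candidate fits were produced on different data."""


@dataclass
class ScalingFit:
    """One fitted scaling law (either candidate or the selected model).

    ``ci95`` maps parameter name -> (low, high); ``alternatives`` holds both
    candidate fits after model selection for audit.
    """

    indicator: str
    model: str  # "single" | "segmented"
    log_y0: float
    beta: float | None = None
    beta_L: float | None = None
    beta_H: float | None = None
    log_d_star: float | None = None
    se_log_d_star: float | None = None
    log_y1: float | None = None
    se_beta: float | None = None
    se_beta_L: float | None = None
    se_beta_H: float | None = None
    ci95: dict = field(default_factory=dict)
    davies_p: float | None = None
    aic: float = np.nan
    bic: float = np.nan
    n_used: int = 0
    residual_sd: float = np.nan
    rss: float = np.nan
    boundary: bool = False
    alternatives: dict | None = None

    @property
    def d_star(self) -> float | None:
        return None if self.log_d_star is None else 10.0 ** self.log_d_star

    def predict(self, log_d) -> np.ndarray:
        """Mean log10 y under the fitted law."""
        x = np.asarray(log_d, dtype=float)
        if self.model == "single":
            return self.log_y0 + self.beta * x
        hinge = np.maximum(0.0, x - self.log_d_star)
        return self.log_y0 + self.beta_L * x + (self.beta_H - self.beta_L) * hinge


def _gaussian_ic(rss: float, n: int, k: int) -> tuple[float, float]:
    # k counts mean-model parameters plus the residual variance
    if rss <= 0:
        rss = np.finfo(float).tiny
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return 2 * k - 2 * ll, k * np.log(n) - 2 * ll


def _clean_xy(log_d, log_y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(log_d, dtype=float)
    y = np.asarray(log_y, dtype=float)
    if x.shape != y.shape:
        raise ConsistencyError("log_d and log_y have different lengths")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares returning (coef, rss, XtX_inv); raises on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError("rank-deficient design (constant regressor?)")
    resid = y - X @ coef
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    return coef, rss, xtx_inv


def fit_single(log_d, log_y, indicator: str = "") -> ScalingFit:
    """OLS fit of the single power law on log10 scales.

    Slope = beta, intercept = log10 y0; standard errors and 95% CIs from the
    regression; AIC/BIC from the Gaussian likelihood.
    """
    x, y = _clean_xy(log_d, log_y)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"single fit needs >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("log_d has zero variance")
    X = np.column_stack([np.ones(n), x])
    coef, rss, xtx_inv = _ols(X, y)
    dof = n - 2
    s2 = rss / dof if dof > 0 else 0.0
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    aic, bic = _gaussian_ic(rss, n, k=3)
    return ScalingFit(
        indicator=indicator,
        model="single",
        log_y0=float(coef[0]),
        beta=float(coef[1]),
        se_beta=float(se[1]),
        ci95={
            "beta": (float(coef[1] - tcrit * se[1]), float(coef[1] + tcrit * se[1])),
            "log_y0": (float(coef[0] - tcrit * se[0]), float(coef[0] + tcrit * se[0])),
        },
        aic=aic,
        bic=bic,
        n_used=n,
        residual_sd=float(np.sqrt(rss / n)),
        rss=rss,
    )


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def profile_rss(log_d, log_y, psis) -> np.ndarray:
    """RSS of the hinge model at each candidate break (brute-force profile)."""
    x, y = _clean_xy(log_d, log_y)
    return np.array([_hinge_rss(x, y, p) for p in np.asarray(psis, float)])


def fit_segmented(
    log_d,
    log_y,
    indicator: str = "",
    grid_points: int = 200,
    quantile_range: tuple[float, float] = (0.02, 0.98),
    refine_tol: float = 1e-8,
) -> ScalingFit:
    """Continuity-constrained two-segment fit with profiled break location.

    Candidate breaks are ``grid_points`` quantiles of log10 d between the
    2nd and 98th percentiles; the minimum-RSS grid cell is refined by
    golden-section search.  A minimum on the grid boundary sets
    ``boundary=True`` (a break at the data edge is unidentifiable and such
    fits are demoted during model selection).  The standard error of
    log10 d* comes from the delta method on the hinge parameterisation.
    """
    x, y = _clean_xy(log_d, log_y)
    n = len(x)
    if n < 10:
        raise InsufficientDataError(f"segmented fit needs >= 10 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("log_d has zero variance")

    qs = np.linspace(quantile_range[0], quantile_range[1], grid_points)
    cand = np.unique(np.quantile(x, qs))
    rss_grid = np.array([_hinge_rss(x, y, p) for p in cand])
    i = int(np.argmin(rss_grid))
    boundary = i == 0 or i == len(cand) - 1

    if not boundary:
        res = optimize.minimize_scalar(
            lambda p: _hinge_rss(x, y, p),
            bracket=(cand[i - 1], cand[i], cand[i + 1]),
            method="golden",
            options={"xtol": refine_tol},
        )
        psi = float(res.x)
        if not (cand[0] <= psi <= cand[-1]) or res.fun > rss_grid[i]:
            psi = float(cand[i])
    else:
        psi = float(cand[i])

    X = np.column_stack([np.ones(n), x, np.maximum(0.0, x - psi)])
    coef, rss, xtx_inv = _ols(X, y)
    a, b, c = coef
    dof = n - 4  # intercept, slope, hinge coefficient, break

    # Standard errors from the break-augmented design {1, x, hinge, -1(x>psi)}:
    # the gap regressor spans the psi direction, so this covariance carries
    # the break-location uncertainty into the slope SEs (delta method on the
    # hinge parameterisation); conditioning on psi-hat alone undercovers the
    # upper slope badly.
    gap = -(x > psi).astype(float)
    Xg = np.column_stack([X, gap])
    try:
        _, rss_g, xtx_inv_g = _ols(Xg, y)
        s2_g = rss_g / (n - 5) if n > 5 else 0.0
        cov = s2_g * xtx_inv_g
        se_bL = float(np.sqrt(max(cov[1, 1], 0.0)))
        se_bH = float(np.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0)))
        se_gap = float(np.sqrt(max(cov[3, 3], 0.0)))
        se_psi = se_gap / abs(c) if c != 0 else np.inf
    except (DegenerateDesignError, np.linalg.LinAlgError):
        s2 = rss / dof if dof > 0 else 0.0
        cov = s2 * xtx_inv
        se_bL = float(np.sqrt(max(cov[1, 1], 0.0)))
        se_bH = float(np.sqrt(max(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2], 0.0)))
        se_psi = np.inf

    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    aic, bic = _gaussian_ic(rss, n, k=5)
    beta_L, beta_H = float(b), float(b + c)
    return ScalingFit(
        indicator=indicator,
        model="segmented",
        log_y0=float(a),
        beta_L=beta_L,
        beta_H=beta_H,
        log_d_star=psi,
        se_log_d_star=se_psi,
        log_y1=float(a - c * psi),
        se_beta_L=se_bL,
        se_beta_H=se_bH,
        ci95={
            "beta_L": (beta_L - tcrit * se_bL, beta_L + tcrit * se_bL),
            "beta_H": (beta_H - tcrit * se_bH, beta_H + tcrit * se_bH),
            "log_d_star": (psi - 1.959963984540054 * se_psi, psi + 1.959963984540054 * se_psi),
        },
        aic=aic,
        bic=bic,
        n_used=n,
        residual_sd=float(np.sqrt(rss / n)),
        rss=rss,
        boundary=boundary,
    )


def davies_test(log_d, log_y, k_points: int = 10) -> float:
    """Upper-bound p-value for a change of slope at an unknown break.

    At each of ``k_points`` interior-quantile candidate breaks the Wald
    statistic of the hinge coefficient is computed; Davies' (1987) bound for
    the supremum of a Gaussian process over the nuisance range gives

        p <= 2 Phi(-M) + V exp(-M^2 / 2) / sqrt(8 pi)

    with M the largest absolute statistic and V the total variation of the
    statistic sequence.  Returns a p-value in (0, 1].
    """
    x, y = _clean_xy(log_d, log_y)
    n = len(x)
    if n < 10:
        raise InsufficientDataError(f"davies test needs >= 10 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("log_d has zero variance")
    psis = np.unique(np.quantile(x, np.linspace(0.05, 0.95, k_points)))
    tstats = []
    for psi in psis:
        X = np.column_stack([np.ones(n), x, np.maximum(0.0, x - psi)])
        try:
            coef, rss, xtx_inv = _ols(X, y)
        except DegenerateDesignError:
            continue
        dof = n - 3
        s2 = rss / dof if dof > 0 else 0.0
        se_c = np.sqrt(max(s2 * xtx_inv[2, 2], 0.0))
        if se_c == 0:
            tstats.append(np.sign(coef[2]) * 1e6)
        else:
            tstats.append(coef[2] / se_c)
    if not tstats:
        raise DegenerateDesignError("no admissible break candidates")
    t = np.asarray(tstats)
    m = float(np.max(np.abs(t)))
    v = float(np.sum(np.abs(np.diff(t))))
    p = 2.0 * stats.norm.sf(m) + v * np.exp(-0.5 * m * m) / np.sqrt(8.0 * np.pi)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def select_model(
    single: ScalingFit,
    segmented: ScalingFit,
    davies_p: float,
    alpha: float = 0.01,
) -> ScalingFit:
    """Gate rule: segmented iff Davies rejects at ``alpha`` AND BIC prefers it.

    Boundary-optimum segmented fits are demoted to single.  Both candidates
    are retained in ``alternatives`` for audit.
    """
    if single.n_used != segmented.n_used:
        raise ConsistencyError("candidate fits used different numbers of points")
    take_seg = (
        davies_p < alpha and segmented.bic < single.bic and not segmented.boundary
    )
    chosen = segmented if take_seg else single
    return dataclasses.replace(
        chosen,
        davies_p=davies_p,
        alternatives={"single": single, "segmented": segmented},
    )


@dataclass
class FitTable:
    """Selected fits for all indicators of a density matrix."""

    fits: dict[str, ScalingFit]

    def __getitem__(self, indicator: str) -> ScalingFit:
        return self.fits[indicator]

    def __iter__(self):
        return iter(self.fits.values())

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def segmented(self) -> list[ScalingFit]:
        return [f for f in self.fits.values() if f.model == "segmented"]

    @property
    def n_segmented(self) -> int:
        return len(self.segmented)

    def d_star_values(self) -> pd.Series:
        """Critical densities (p/ha) of the segmented indicators, for rank/histogram views."""
        return pd.Series(
            {f.indicator: f.d_star for f in self.segmented}, dtype=float
        ).sort_values()

    @property
    def median_d_star(self) -> float:
        vals = self.d_star_values()
        return float(vals.median()) if len(vals) else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits.values():
            alt = f.alternatives or {}
            rows.append(
                {
                    "indicator": f.indicator,
                    "model": f.model,
                    "beta": f.beta,
                    "beta_L": f.beta_L,
                    "beta_H": f.beta_H,
                    "d_star": f.d_star,
                    "log_d_star": f.log_d_star,
                    "se_log_d_star": f.se_log_d_star,
                    "log_y0": f.log_y0,
                    "davies_p": f.davies_p,
                    "aic_single": alt["single"].aic if alt else None,
                    "bic_single": alt["single"].bic if alt else None,
                    "aic_segmented": alt["segmented"].aic if alt and "segmented" in alt else None,
                    "bic_segmented": alt["segmented"].bic if alt and "segmented" in alt else None,
                    "n_used": f.n_used,
                    "residual_sd": f.residual_sd,
                    "ci95": {k: list(v) for k, v in f.ci95.items()},
                }
            )
        return pd.DataFrame(rows).set_index("indicator")

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["ci95"] = df["ci95"].map(lambda d: ";".join(f"{k}={lo:.6g}..{hi:.6g}" for k, (lo, hi) in d.items()))
        df.to_csv(path)


def fit_all_indicators(
    dm: DensityMatrix,
    alpha: float = 0.01,
    davies_k: int = 10,
    min_n: int = 10,
) -> FitTable:
    """Fit and select the scaling model for every indicator in a density matrix.

    Zero-count cells (missing logs) are excluded per indicator; an indicator
    with fewer than ``min_n`` usable cells falls back to the single fit (or
    is skipped entirely with a warning when fewer than 3 remain).
    """
    if not dm.indicators:
        raise InsufficientDataError("density matrix has no indicators")
    fits: dict[str, ScalingFit] = {}
    for name in dm.indicators:
        x = dm.log_d.to_numpy()
        y = dm.log_y[name].to_numpy()
        keep = np.isfinite(x) & np.isfinite(y)
        n = int(keep.sum())
        if n < 3:
            logger.warning("indicator %r skipped: only %d usable cells", name, n)
            continue
        if n < min_n:
            logger.warning("indicator %r: %d cells, single model only", name, n)
            fits[name] = fit_single(x[keep], y[keep], indicator=name)
            continue
        single = fit_single(x[keep], y[keep], indicator=name)
        segmented = fit_segmented(x[keep], y[keep], indicator=name)
        p = davies_test(x[keep], y[keep], k_points=davies_k)
        fits[name] = select_model(single, segmented, p, alpha=alpha)
    return FitTable(fits=fits)
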