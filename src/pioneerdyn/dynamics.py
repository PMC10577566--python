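"""Per-peak accessibility-change kinetics.

Normalized counts for each dynamic peak are rescaled to [0, 1] and fitted
with the five-parameter log-logistic family

    f(t) = A + (K - A) / (1 + (t / T50)^B)^f

in several parameterizations (B and T50 always free; A, K and f either
free or fixed at 0, 1 and 1). The form in (t/T50)^B is algebraically the
classical exp(B(log t - log T50)) parameterization but remains finite at
t = 0 (value K for B > 0), so the untreated sample participates in the fit.
Candidate models compete by AIC: among log-logistic variants the simpler
wins when dAIC < 2; against polynomial nulls the asymmetric rule applies —
0th/1st-degree polynomials are preferred over log-logistic when dAIC < 2,
while the log-logistic is preferred over the 2nd-degree polynomial when
dAIC < 2. T50 is reported only when a log-logistic variant wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_core import CountMatrix

__all__ = [
    "DynamicsFit",
    "ModelChoice",
    "rescale_unit_interval",
    "fit_log_logistic",
    "select_model",
    "estimate_t50_table",
    "t50_density",
]

logger = logging.getLogger(__name__)

LOG_LOGISTIC_VARIANTS = {
    # name -> which of (A, K, f) are free
    "LL2": (),  # A=0, K=1, f=1 fixed; free: B, T50
    "LL3": ("A",),  # free lower asymptote (rescaling shifts it); K=1, f=1
    "LL4": ("A", "K"),  # free: A, K, B, T50
    "LL5": ("A", "K", "f"),  # free: A, K, B, T50, f
}

_B_GRID = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
_T50_GRID = np.geomspace(0.05, 48.0, 16)
# box constraints keep the exp-parameterization finite
_BOUNDS = {
    "logB": (np.log(0.02), np.log(100.0)),
    "logT50": (np.log(1e-3), np.log(1e3)),
    "A": (-3.0, 3.0),
    "K": (-3.0, 4.0),
    "logf": (np.log(0.05), np.log(20.0)),
}


def log_logistic(t, A, K, B, T50, f=1.0):
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        denom = (1.0 + (t / T50) ** B) ** f
        out = A + (K - A) / denom
    # extreme-B overflow: the curve saturates at its asymptotes
    return np.where(np.isfinite(out), out, A)


@dataclass
class DynamicsFit:
    A: float
    K: float
    B: float
    T50: float
    f: float
    fixed_mask: tuple[str, ...]
    rss: float
    aic: float
    converged: bool
    n_free: int

    @property
    def direction(self) -> str:
        return "down" if self.K > self.A else "up"


@dataclass
class ModelChoice:
    chosen: str  # LL2/LL4/LL5 or poly0/poly1/poly2
    delta_aic_vs_runnerup: float
    fit: DynamicsFit | None = None

    @property
    def is_log_logistic(self) -> bool:
        return self.chosen.startswith("LL")

    @property
    def t50_reported(self) -> float | None:
        return self.fit.T50 if self.is_log_logistic and self.fit else None


def rescale_unit_interval(y: np.ndarray) -> np.ndarray:
    """Affine map of a series onto [0, 1]; errors on constant input."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("constant series cannot be rescaled; route to poly0")
    return (y - lo) / (hi - lo)


def _aic(rss: float, n: int, n_free: int) -> float:
    """Gaussian AIC with the error variance profiled out.

    p counts the free mean parameters plus sigma; the additive constant
    n*(log(2*pi) + 1) is shared by all candidates and omitted.
    """
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (n_free + 1)


def _grid_seed(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best (B, T50) on a coarse vectorized grid with A=0, K=1, f=1."""
    B = _B_GRID[:, None, None]
    T50 = _T50_GRID[None, :, None]
    pred = 1.0 / (1.0 + (t[None, None, :] / T50) ** B)
    rss = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(_B_GRID[i]), float(_T50_GRID[j])


def fit_log_logistic(
    t: np.ndarray,
    y: np.ndarray,
    free: tuple[str, ...] = (),
    seed_fit: "DynamicsFit | None" = None,
) -> DynamicsFit:
    """Least-squares log-logistic fit, seeded from a coarse (B, T50) grid.

    `free` lists which of A, K, f are estimated; the rest are fixed at
    0, 1, 1. B and T50 are always estimated. `seed_fit` optionally warm-
    starts the optimizer from a simpler variant's solution. Failure to
    converge yields converged=False with infinite AIC.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    n_free = 2 + len(free)
    if n <= n_free:
        return DynamicsFit(0, 1, np.nan, np.nan, 1, tuple(free), np.inf, np.inf, False, n_free)

    est_A = "A" in free
    est_K = "K" in free
    est_f = "f" in free

    def unpack(theta):
        logB, logT50 = theta[0], theta[1]
        i = 2
        A = theta[i] if est_A else 0.0
        i += est_A
        K = theta[i] if est_K else 1.0
        i += est_K
        f = np.exp(theta[i]) if est_f else 1.0
        return A, K, np.exp(logB), np.exp(logT50), f

    def residuals(theta):
        A, K, B, T50, f = unpack(theta)
        return log_logistic(t, A, K, B, T50, f) - y

    lo, hi = [], []
    for key in ["logB", "logT50"] + (["A"] if est_A else []) + (["K"] if est_K else []) + (
        ["logf"] if est_f else []
    ):
        lo.append(_BOUNDS[key][0])
        hi.append(_BOUNDS[key][1])

    if seed_fit is not None and seed_fit.converged:
        B0, T0 = seed_fit.B, seed_fit.T50
        A0, K0, f0 = seed_fit.A, seed_fit.K, seed_fit.f
    else:
        B0, T0 = _grid_seed(t, y)
        A0, K0, f0 = float(y[-1]), float(y[0]), 1.0
    theta0 = [np.log(B0), np.log(T0)]
    if est_A:
        theta0.append(A0)
    if est_K:
        theta0.append(K0)
    if est_f:
        theta0.append(np.log(max(f0, 0.1)))
    theta0 = np.clip(theta0, lo, hi)

    best = None
    for start in (theta0,):
        try:
            sol = least_squares(
                residuals, start, bounds=(lo, hi), method="trf", max_nfev=300
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol.x)
    if best is None:
        return DynamicsFit(0, 1, np.nan, np.nan, 1, tuple(free), np.inf, np.inf, False, n_free)
    rss, theta = best
    A, K, B, T50, f = unpack(theta)
    return DynamicsFit(
        A=float(A),
        K=float(K),
        B=float(B),
        T50=float(T50),
        f=float(f),
        fixed_mask=tuple(x for x in ("A", "K", "f") if x not in free),
        rss=rss,
        aic=_aic(rss, n, n_free),
        converged=True,
        n_free=n_free,
    )


def _fit_poly(t: np.ndarray, y: np.ndarray, degree: int) -> tuple[float, float]:
    """Least-squares polynomial fit; returns (rss, aic)."""
    coef = np.polyfit(t, y, degree)
    rss = float(np.sum((np.polyval(coef, t) - y) ** 2))
    return rss, _aic(rss, t.size, degree + 1)


def select_model(t: np.ndarray, y: np.ndarray) -> ModelChoice:
    """AIC competition between log-logistic variants and polynomial nulls.

    Among converged log-logistic variants the one with fewest free
    parameters whose AIC is within 2 of the best is retained. The
    asymmetric polynomial rule then applies: poly0 or poly1 is chosen when
    its AIC is less than the retained log-logistic AIC + 2; otherwise the
    log-logistic is kept unless the 2nd-degree polynomial beats it by 2 or
    more.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    if np.ptp(y) == 0:
        return ModelChoice(chosen="poly0", delta_aic_vs_runnerup=np.inf)

    ll_fits: dict[str, DynamicsFit] = {}
    warm: DynamicsFit | None = None
    for name, free in LOG_LOGISTIC_VARIANTS.items():
        fit = fit_log_logistic(t, y, free, seed_fit=warm)
        if fit.converged and np.isfinite(fit.aic):
            ll_fits[name] = fit
            warm = fit

    poly_aic = {f"poly{d}": _fit_poly(t, y, d)[1] for d in (0, 1, 2) if t.size > d + 1}

    if not ll_fits:
        chosen = min(poly_aic, key=poly_aic.get)
        rest = sorted(poly_aic.values())
        delta = rest[1] - rest[0] if len(rest) > 1 else np.inf
        return ModelChoice(chosen=chosen, delta_aic_vs_runnerup=delta)

    # simplest log-logistic within 2 AIC of the best variant
    best_ll_aic = min(f.aic for f in ll_fits.values())
    candidates = [k for k, f in ll_fits.items() if f.aic - best_ll_aic < 2.0]
    ll_name = min(candidates, key=lambda k: (ll_fits[k].n_free, ll_fits[k].aic))
    ll = ll_fits[ll_name]

    # asymmetric rule against polynomial nulls
    for simple in ("poly0", "poly1"):
        if simple in poly_aic and poly_aic[simple] - ll.aic < 2.0:
            return ModelChoice(
                chosen=simple,
                delta_aic_vs_runnerup=abs(poly_aic[simple] - ll.aic),
            )
    if "poly2" in poly_aic and ll.aic - poly_aic["poly2"] >= 2.0:
        return ModelChoice(
            chosen="poly2", delta_aic_vs_runnerup=ll.aic - poly_aic["poly2"]
        )
    runner = min(
        [poly_aic.get("poly2", np.inf)]
        + [f.aic for k, f in ll_fits.items() if k != ll_name]
    )
    return ModelChoice(
        chosen=ll_name, delta_aic_vs_runnerup=abs(runner - ll.aic), fit=ll
    )


def estimate_t50_table(
    counts: CountMatrix,
    timepoints: np.ndarray,
    dar_flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize -> rescale -> model-select per flagged peak.

    `dar_flags` marks the peaks that passed the upstream dynamic-peak
    pre-selection (a likelihood-ratio test across time, consumed as a flag
    column here). Returns a table with the chosen model, parameters and
    T50 (NaN unless a log-logistic variant won). Peaks with fewer than 4
    usable timepoints are skipped with a log entry.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if counts.size_factors is None:
        raise ValueError("size factors must be estimated before fitting")
    norm = counts.normalized()
    if dar_flags is None:
        ids = list(norm.index)
    else:
        ids = list(dar_flags.index[dar_flags.astype(bool)])
    rows = []
    for pid in ids:
        y = norm.loc[pid].to_numpy(dtype=float)
        usable = np.isfinite(y)
        if usable.sum() < 4:
            logger.info("peak %s skipped: <4 usable timepoints", pid)
            continue
        t, yy = timepoints[usable], y[usable]
        if np.ptp(yy) == 0:
            rows.append((pid, "poly0", *[np.nan] * 5, np.inf, "down"))
            continue
        # rescale against per-timepoint replicate means (replicate noise
        # should not set the [0, 1] anchors)
        tp_means = pd.Series(yy).groupby(pd.Series(t)).mean()
        lo, hi = tp_means.min(), tp_means.max()
        if hi == lo:
            rows.append((pid, "poly0", *[np.nan] * 5, np.inf, "down"))
            continue
        ys = (yy - lo) / (hi - lo)
        # orient so the fixed-parameter variant (start 1, end 0) applies to
        # both losses and gains; direction recorded from the raw series
        direction = "down" if tp_means.iloc[-1] < tp_means.iloc[0] else "up"
        if direction == "up":
            ys = 1.0 - ys
        choice = select_model(t, ys)
        fit = choice.fit
        rows.append(
            (
                pid,
                choice.chosen,
                fit.A if fit else np.nan,
                fit.K if fit else np.nan,
                fit.B if fit else np.nan,
                fit.f if fit else np.nan,
                choice.t50_reported if choice.t50_reported is not None else np.nan,
                choice.delta_aic_vs_runnerup,
                direction,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "chosen_model", "A", "K", "B", "f", "T50", "delta_aic", "direction"],
    ).set_index("peak_id")


def t50_density(
    t50_values: np.ndarray, grid: np.ndarray | None = None, bandwidth: float = 0.25
) -> pd.DataFrame:
    """Gaussian KDE of asinh-transformed T50, area scaled to the number of
    contributing peaks (so the curve integrates to the DAR count)."""
    x = np.asinh(np.asarray(t50_values, dtype=float))
    x = x[np.isfinite(x)]
    if x.size == 0:
        return pd.DataFrame(columns=["asinh_t50", "density"])
    if grid is None:
        grid = np.linspace(x.min() - 1, x.max() + 1, 256)
    diffs = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * diffs**2).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi))
    return pd.DataFrame({"asinh_t50": grid, "density": dens})
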