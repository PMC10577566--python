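"""Matched-control construction.

Two samplers: expression-matched stable genes (density-weighted draws from
the pool accepted by a two-sample Kolmogorov-Smirnov criterion, resampled
many times to propagate control-set variability) and covariate-stratified
peak matching on quantile strata (the 'partially matched' behavior is
operationalized by a borrowed-strata diagnostic when a stratum's pool is
too small).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

__all__ = ["MatchResult", "match_genes_expression", "match_peaks_stratified"]


@dataclass
class MatchResult:
    control_ids: list[str]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_resample: int = 1
    borrowed: int = 0
    n_attempts: int = 1


def _density_weights(case_values: np.ndarray, pool_values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Pool sampling weights proportional to case density over pool density,
    on case-quantile bins of the matching variable."""
    qs = np.quantile(case_values, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    case_bin = np.clip(np.searchsorted(qs, case_values, side="right") - 1, 0, n_bins - 1)
    pool_bin = np.clip(np.searchsorted(qs, pool_values, side="right") - 1, 0, n_bins - 1)
    case_counts = np.bincount(case_bin, minlength=n_bins).astype(float)
    pool_counts = np.bincount(pool_bin, minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pool_counts > 0, case_counts / pool_counts, 0.0)
    w = ratio[pool_bin]
    if w.sum() == 0:
        w = np.ones_like(w)
    return w / w.sum()


def match_genes_expression(
    cases: pd.Series,
    pool: pd.Series,
    n_draws: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    retry_cap: int = 1_000,
) -> list[MatchResult]:
    """Draw `n_draws` expression-matched control sets from the stable pool.

    Each draw samples len(cases) controls without replacement, weighted so
    the pool's expression distribution locally matches the cases', and is
    accepted when the two-sample KS test fails to reject equality
    (p > alpha). Case and pool indices must be disjoint.
    """
    if len(pool) < len(cases):
        raise ValueError("pool must be larger than the case set")
    overlap = set(cases.index) & set(pool.index)
    if overlap:
        raise ValueError(f"case/pool ids overlap: {sorted(overlap)[:3]}...")
    rng = np.random.default_rng(seed)
    cv = cases.to_numpy(dtype=float)
    pv = pool.to_numpy(dtype=float)
    weights = _density_weights(cv, pv)
    results: list[MatchResult] = []
    best_p = 0.0
    for _ in range(n_draws):
        accepted = None
        for attempt in range(1, retry_cap + 1):
            idx = rng.choice(len(pv), size=len(cv), replace=False, p=weights)
            stat, p = ks_2samp(cv, pv[idx])
            best_p = max(best_p, p)
            if p > alpha:
                accepted = (idx, stat, p, attempt)
                break
        if accepted is None:
            raise RuntimeError(
                f"KS acceptance not reached within {retry_cap} tries "
                f"(best p = {best_p:.4g})"
            )
        idx, stat, p, attempt = accepted
        results.append(
            MatchResult(
                control_ids=list(pool.index[idx]),
                diagnostics=pd.DataFrame(
                    {"covariate": ["expression"], "ks_stat": [stat], "ks_p": [p]}
                ),
                n_resample=n_draws,
                n_attempts=attempt,
            )
        )
    return results


def match_peaks_stratified(
    focal: pd.DataFrame,
    pool: pd.DataFrame,
    n_strata: int = 10,
    seed: int = 0,
    max_cells: int = 100,
) -> MatchResult:
    """Covariate-matched controls by joint quantile stratification.

    `focal` and `pool` are id-indexed frames of matching covariates (e.g.
    log10(1 + max coverage) of accessibility and factor-binding tracks).
    The joint covariate space is cut into per-covariate quantile strata
    (total cells capped); controls are drawn per cell to mirror the focal
    occupancy, borrowing from the nearest cells when a cell's pool is
    exhausted. Borrowed draws are counted in the diagnostics.
    """
    if focal.empty or pool.empty:
        raise ValueError("focal and pool must be nonempty")
    overlap = set(focal.index) & set(pool.index)
    if overlap:
        raise ValueError("focal/pool ids must be disjoint")
    covs = list(focal.columns)
    per_cov = max(2, min(n_strata, int(max_cells ** (1 / len(covs)))))

    def strat_codes(df: pd.DataFrame) -> np.ndarray:
        codes = np.zeros(len(df), dtype=int)
        for c in covs:
            qs = np.quantile(focal[c].to_numpy(float), np.linspace(0, 1, per_cov + 1))
            qs[0], qs[-1] = -np.inf, np.inf
            b = np.clip(
                np.searchsorted(qs, df[c].to_numpy(float), side="right") - 1,
                0,
                per_cov - 1,
            )
            codes = codes * per_cov + b
        return codes

    rng = np.random.default_rng(seed)
    f_codes = strat_codes(focal)
    p_codes = strat_codes(pool)
    pool_ids = np.asarray(pool.index)
    cell_ids = np.arange(per_cov ** len(covs))
    cell_coords = np.stack(
        np.unravel_index(cell_ids, (per_cov,) * len(covs)), axis=1
    )
    available = {c: list(np.flatnonzero(p_codes == c)) for c in cell_ids}
    for c in available:
        rng.shuffle(available[c])

    chosen: list[int] = []
    borrowed = 0
    for cell, need in zip(*np.unique(f_codes, return_counts=True)):
        got = 0
        # own cell first
        take = min(need, len(available[cell]))
        for _ in range(take):
            chosen.append(available[cell].pop())
        got += take
        if got < need:
            # borrow from nearest cells by stratum-coordinate distance
            dists = np.abs(cell_coords - cell_coords[cell]).sum(axis=1)
            for other in np.argsort(dists, kind="stable"):
                if other == cell:
                    continue
                while got < need and available[other]:
                    chosen.append(available[other].pop())
                    got += 1
                    borrowed += 1
                if got == need:
                    break
        if got < need:
            raise ValueError("pool exhausted: cannot match focal set size")
    control_idx = np.asarray(chosen)
    diag_rows = []
    for c in covs:
        stat, p = ks_2samp(
            focal[c].to_numpy(float), pool[c].to_numpy(float)[control_idx]
        )
        diag_rows.append((c, stat, p))
    return MatchResult(
        control_ids=list(pool_ids[control_idx]),
        diagnostics=pd.DataFrame(diag_rows, columns=["covariate", "ks_stat", "ks_p"]),
        borrowed=borrowed,
    )
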