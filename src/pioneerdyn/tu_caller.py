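"""Transcribed-unit calling from stranded nascent-RNA fragment data.

Pooled fragment midpoints are counted in 200 bp bins per strand and
discretized into low/high transcriptional states with a 2-state hidden
Markov model whose emissions are Poisson-lognormal: conditional on a
lognormal rate exp(mu + sigma*Z), the bin count is Poisson. The marginal
emission likelihood is evaluated by Gauss-Hermite quadrature. Runs of
high-state bins (ignoring single-bin interruptions) become putative TUs,
which are then fragment-filtered, refined to basepair precision from
per-bp coverage steps, associated with genes by same-strand overlap,
split at internal TSSs followed by a transcription wave, and count-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .io_core import CoverageTrack, GenomicInterval

__all__ = [
    "HMMParams",
    "TUCallerConfig",
    "TranscribedUnit",
    "poisson_lognormal_loglik",
    "forward_loglik",
    "fit_hmm",
    "decode_states",
    "states_to_putative_tus",
    "filter_putative_tus",
    "refine_boundaries",
    "associate_tus_genes",
    "split_tus_at_internal_tss",
    "count_and_filter_tus",
    "call_tus",
]


@dataclass
class HMMParams:
    """2-state HMM: state 0 = low, state 1 = high (mu_high > mu_low)."""

    initial: np.ndarray
    transition: np.ndarray
    mu: np.ndarray  # lognormal log-rate means, per state
    sigma: np.ndarray  # lognormal log-rate sds, per state

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")

    def relabeled(self) -> "HMMParams":
        """Ensure state 1 has the higher log-rate mean."""
        if self.mu[1] >= self.mu[0]:
            return self
        perm = [1, 0]
        return HMMParams(
            initial=self.initial[perm],
            transition=self.transition[np.ix_(perm, perm)],
            mu=self.mu[perm],
            sigma=self.sigma[perm],
        )


@dataclass
class TUCallerConfig:
    bin_size: int = 200
    min_fragments_putative: int = 25
    refine_window: int = 400
    refine_step_threshold: float = 1.0
    jaccard_small_gene: float = 0.02
    split_window: int = 2_000
    split_median_increase: float = 5.0
    min_count_filter: int = 10
    min_samples_filter: int = 2
    gh_nodes: int = 20
    em_tol: float = 1e-6
    em_max_iter: int = 200

    def __post_init__(self) -> None:
        for name in (
            "bin_size",
            "min_fragments_putative",
            "refine_window",
            "split_window",
            "min_count_filter",
            "min_samples_filter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TranscribedUnit:
    interval: GenomicInterval
    state_support: int = 0
    fragment_counts: dict[str, int] = field(default_factory=dict)
    gene_ids: list[str] = field(default_factory=list)
    multi_small_flag: bool = False


# ---------------------------------------------------------------------------
# Poisson-lognormal emission
# ---------------------------------------------------------------------------

def poisson_lognormal_loglik(
    counts: np.ndarray, mu: float, sigma: float, n_nodes: int = 20
) -> np.ndarray:
    """log P(X = x) for X ~ Poisson(exp(mu + sigma*Z)), Z ~ N(0,1).

    Gauss-Hermite quadrature: with nodes/weights for exp(-t^2),
    E[g(Z)] = sum_j w_j g(sqrt(2) t_j) / sqrt(pi).
    """
    counts = np.asarray(counts)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_rate = mu + sigma * np.sqrt(2.0) * nodes  # (n_nodes,)
    x = counts[..., None]
    log_pois = x * log_rate - np.exp(log_rate) - gammaln(x + 1.0)
    return logsumexp(log_pois + np.log(weights), axis=-1) - 0.5 * np.log(np.pi)


def _emission_matrix(counts: np.ndarray, params: HMMParams, n_nodes: int) -> np.ndarray:
    """(T, 2) log-emission probabilities, memoized over unique counts."""
    uniq, inv = np.unique(counts, return_inverse=True)
    out = np.empty((uniq.size, 2))
    for s in range(2):
        out[:, s] = poisson_lognormal_loglik(uniq, params.mu[s], params.sigma[s], n_nodes)
    return out[inv]


# ---------------------------------------------------------------------------
# forward / backward / EM
# ---------------------------------------------------------------------------

def _forward_backward(log_b: np.ndarray, params: HMMParams):
    T = log_b.shape[0]
    log_pi = np.log(params.initial + 1e-300)
    log_A = np.log(params.transition + 1e-300)
    log_alpha = np.empty((T, 2))
    log_alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        log_alpha[t] = log_b[t] + logsumexp(log_alpha[t - 1][:, None] + log_A, axis=0)
    log_beta = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(log_A + (log_b[t + 1] + log_beta[t + 1])[None, :], axis=1)
    loglik = logsumexp(log_alpha[-1])
    log_gamma = log_alpha + log_beta - loglik
    return log_alpha, log_beta, log_gamma, loglik


def forward_loglik(counts: np.ndarray, params: HMMParams, n_nodes: int = 20) -> float:
    """Total log-likelihood of a bin-count chain under the HMM."""
    log_b = _emission_matrix(np.asarray(counts), params, n_nodes)
    return float(_forward_backward(log_b, params)[3])


def _init_params(counts: np.ndarray, seed: int = 0) -> HMMParams:
    """2-means split of log1p counts for initial emission parameters."""
    x = np.log1p(np.asarray(counts, dtype=float))
    med = np.median(x)
    lo = x[x <= med]
    hi = x[x > med]
    if hi.size == 0:  # degenerate all-equal input
        hi = lo
    # crude moment init on the log1p scale, floored for stability
    mu = np.array([np.mean(lo) - 0.5, np.mean(hi) + 0.5])
    sigma = np.array(
        [max(np.std(lo), 0.3), max(np.std(hi), 0.3)]
    )
    return HMMParams(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.95, 0.05], [0.05, 0.95]]),
        mu=mu,
        sigma=sigma,
    ).relabeled()


def fit_hmm(
    counts: np.ndarray,
    init: HMMParams | None = None,
    cfg: TUCallerConfig | None = None,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch EM with Poisson-lognormal emissions.

    The M-step for (mu, sigma) maximizes the expected emission
    log-likelihood numerically (generalized EM); a candidate update is
    only accepted if it does not decrease the expected objective, so the
    data log-likelihood is non-decreasing across iterations up to
    quadrature error. Returns (params, per-iteration log-likelihoods).
    """
    cfg = cfg or TUCallerConfig()
    counts = np.asarray(counts)
    if counts.max(initial=0) == 0:
        import warnings

        warnings.warn("all-zero input: degenerate single-state fit")
        params = HMMParams(
            initial=np.array([1.0, 0.0]),
            transition=np.array([[1.0, 0.0], [0.5, 0.5]]),
            mu=np.array([-10.0, -9.99]),
            sigma=np.array([0.3, 0.3]),
        )
        return params, [forward_loglik(counts, params, cfg.gh_nodes)]
    params = (init or _init_params(counts)).relabeled()
    logliks: list[float] = []
    for _ in range(cfg.em_max_iter):
        log_b = _emission_matrix(counts, params, cfg.gh_nodes)
        log_alpha, log_beta, log_gamma, loglik = _forward_backward(log_b, params)
        logliks.append(float(loglik))
        if len(logliks) > 1 and logliks[-1] - logliks[-2] < cfg.em_tol:
            break
        gamma = np.exp(log_gamma)
        # transition expectations
        log_A = np.log(params.transition + 1e-300)
        log_xi = (
            log_alpha[:-1, :, None]
            + log_A[None]
            + (log_b[1:] + log_beta[1:])[:, None, :]
            - loglik
        )
        xi = np.exp(logsumexp(log_xi, axis=0))
        new_trans = xi / xi.sum(axis=1, keepdims=True)
        new_init = gamma[0] / gamma[0].sum()

        new_mu = params.mu.copy()
        new_sigma = params.sigma.copy()
        uniq, inv = np.unique(counts, return_inverse=True)
        for s in range(2):
            w = np.bincount(inv, weights=gamma[:, s], minlength=uniq.size)

            def neg_obj(theta, _w=w, _u=uniq):
                m, log_s = theta
                ll = poisson_lognormal_loglik(_u, m, np.exp(log_s), cfg.gh_nodes)
                return -float(np.dot(_w, ll))

            x0 = np.array([params.mu[s], np.log(params.sigma[s])])
            res = minimize(neg_obj, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-6})
            if res.fun <= neg_obj(x0):  # generalized EM: accept only improvements
                new_mu[s] = res.x[0]
                new_sigma[s] = max(np.exp(res.x[1]), 1e-3)
        params = HMMParams(
            initial=new_init, transition=new_trans, mu=new_mu, sigma=new_sigma
        ).relabeled()
    return params, logliks


def decode_states(
    params: HMMParams,
    counts: np.ndarray,
    method: str = "posterior",
    n_nodes: int = 20,
) -> np.ndarray:
    """Per-bin state labels: posterior-marginal argmax (default) or Viterbi.

    Posterior ties go to the low state.
    """
    counts = np.asarray(counts)
    log_b = _emission_matrix(counts, params, n_nodes)
    if method == "posterior":
        _, _, log_gamma, _ = _forward_backward(log_b, params)
        return (log_gamma[:, 1] > log_gamma[:, 0]).astype(int)
    if method == "viterbi":
        T = log_b.shape[0]
        log_pi = np.log(params.initial + 1e-300)
        log_A = np.log(params.transition + 1e-300)
        delta = log_pi + log_b[0]
        back = np.zeros((T, 2), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + log_A
            back[t] = np.argmax(cand, axis=0)
            delta = log_b[t] + np.max(cand, axis=0)
        states = np.empty(T, dtype=int)
        states[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        return states
    raise ValueError(f"unknown decode method {method!r}")


# ---------------------------------------------------------------------------
# TU construction and post-processing
# ---------------------------------------------------------------------------

def merge_single_bin_interruptions(labels: np.ndarray) -> np.ndarray:
    """Absorb isolated single low bins flanked by high bins (H L H -> H H H)."""
    labels = np.asarray(labels, dtype=int).copy()
    interior = np.flatnonzero(
        (labels[1:-1] == 0) & (labels[:-2] == 1) & (labels[2:] == 1)
    )
    labels[interior + 1] = 1
    return labels


def states_to_putative_tus(
    labels: np.ndarray,
    chrom: str,
    strand: str,
    cfg: TUCallerConfig | None = None,
    bin_offset: int = 0,
) -> list[TranscribedUnit]:
    """Maximal high-state runs (single-bin gaps absorbed) as putative TUs."""
    cfg = cfg or TUCallerConfig()
    merged = merge_single_bin_interruptions(labels)
    tus: list[TranscribedUnit] = []
    bs = cfg.bin_size
    padded = np.concatenate([[0], merged, [0]])
    changes = np.flatnonzero(np.diff(padded))
    for lo, hi in zip(changes[::2], changes[1::2]):
        start = (bin_offset + lo) * bs
        end = (bin_offset + hi) * bs
        tus.append(
            TranscribedUnit(
                interval=GenomicInterval(chrom, start, end, strand, f"tu_{chrom}_{strand}_{start}"),
                state_support=int(hi - lo),
            )
        )
    return tus


def _count_overlapping(
    tu: TranscribedUnit, frag_starts: np.ndarray, frag_ends: np.ndarray
) -> int:
    iv = tu.interval
    return int(np.count_nonzero((frag_starts < iv.end) & (frag_ends > iv.start)))


def _frag_arrays(fragments: Sequence[GenomicInterval], chrom: str, strand: str):
    sel = [f for f in fragments if f.chrom == chrom and f.strand == strand]
    return (
        np.array([f.start for f in sel], dtype=int),
        np.array([f.end for f in sel], dtype=int),
    )


def filter_putative_tus(
    tus: Sequence[TranscribedUnit],
    fragments: Sequence[GenomicInterval],
    cfg: TUCallerConfig | None = None,
) -> list[TranscribedUnit]:
    """Keep TUs with strictly more than `min_fragments_putative` overlapping
    strand-matched fragments."""
    cfg = cfg or TUCallerConfig()
    out = []
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for tu in tus:
        key = (tu.interval.chrom, tu.interval.strand)
        if key not in cache:
            cache[key] = _frag_arrays(fragments, *key)
        n = _count_overlapping(tu, *cache[key])
        if n > cfg.min_fragments_putative:
            out.append(tu)
    return out


def refine_boundaries(
    tu: TranscribedUnit,
    coverage: CoverageTrack,
    cfg: TUCallerConfig | None = None,
) -> TranscribedUnit:
    """Refine bin-resolution ends to bp using coverage steps.

    Within a `refine_window` bp window centered on each boundary, the start
    moves to one past the first position where cov[x+1] - cov[x] exceeds
    the threshold; the end (mirrored) moves to one past the last position
    where the decrease exceeds it. Boundaries are unchanged when no
    position qualifies.
    """
    cfg = cfg or TUCallerConfig()
    half = cfg.refine_window // 2
    iv = tu.interval
    thr = cfg.refine_step_threshold

    def diffs_in(lo: int, hi: int) -> tuple[np.ndarray, int]:
        vals = coverage.slice_bp(lo, hi + 1)  # need cov[x+1] for x in [lo, hi)
        return np.diff(vals), lo

    start = iv.start
    d, lo = diffs_in(iv.start - half, iv.start + half)
    rising = np.flatnonzero(d > thr)
    if rising.size:
        start = lo + int(rising[0]) + 1

    end = iv.end
    d, lo = diffs_in(iv.end - half, iv.end + half)
    falling = np.flatnonzero(d < -thr)
    if falling.size:
        end = lo + int(falling[-1]) + 1

    if start >= end:  # refinement collapsed the interval; keep bin extents
        return tu
    return replace(tu, interval=replace(iv, start=start, end=end))


def associate_tus_genes(
    tus: Sequence[TranscribedUnit],
    genes: Sequence[GenomicInterval],
    cfg: TUCallerConfig | None = None,
) -> list[TranscribedUnit]:
    """Attach same-strand overlapping genes; flag TUs covering only small
    genes (every per-gene Jaccard below the threshold, with >1 gene)."""
    cfg = cfg or TUCallerConfig()
    out = []
    for tu in tus:
        iv = tu.interval
        hits = [
            g for g in genes
            if g.strand == iv.strand and g.overlaps(iv)
        ]
        jac = [iv.jaccard(g) for g in hits]
        flag = len(hits) > 1 and all(j < cfg.jaccard_small_gene for j in jac)
        out.append(
            replace(tu, gene_ids=[g.name for g in hits], multi_small_flag=flag)
        )
    return out


def split_tus_at_internal_tss(
    tu: TranscribedUnit,
    genes: Sequence[GenomicInterval],
    coverage: CoverageTrack,
    cfg: TUCallerConfig | None = None,
) -> list[TranscribedUnit]:
    """Split a multi-gene TU at internal TSSs followed by a transcription wave.

    The transcription wave is detected inside the `split_window` centered
    at the internal TSS (strand-aware): the median per-bp coverage over the
    downstream half of that window must exceed the median over the upstream
    (5') half by at least `split_median_increase`. A clean step of +6 at
    the TSS therefore splits, a step of +4 does not. Splits are applied
    5'-to-3'; children partition the parent interval.
    """
    cfg = cfg or TUCallerConfig()
    iv = tu.interval
    by_name = {g.name: g for g in genes}
    assoc = [by_name[n] for n in tu.gene_ids if n in by_name]
    if len(assoc) < 2 or tu.multi_small_flag:
        return [tu]
    half = cfg.split_window // 2
    split_points = []
    for g in assoc:
        tss = g.start if g.strand == "+" else g.end - 1
        if not (iv.start < tss < iv.end - 1):
            continue
        if g.strand == "+":
            downstream = np.median(coverage.slice_bp(tss, tss + half))
            upstream = np.median(coverage.slice_bp(tss - half, tss))
        else:
            downstream = np.median(coverage.slice_bp(tss - half + 1, tss + 1))
            upstream = np.median(coverage.slice_bp(tss + 1, tss + half + 1))
        if downstream - upstream >= cfg.split_median_increase:
            split_points.append(tss)
    if not split_points:
        return [tu]
    split_points = sorted(set(split_points))
    bounds = [iv.start] + split_points + [iv.end]
    children = []
    for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
        children.append(
            replace(
                tu,
                interval=GenomicInterval(iv.chrom, s, e, iv.strand, f"{iv.name}.{i}"),
            )
        )
    return children


def count_and_filter_tus(
    tus: Sequence[TranscribedUnit],
    fragments_by_sample: dict[str, Sequence[GenomicInterval]],
    cfg: TUCallerConfig | None = None,
) -> tuple[list[TranscribedUnit], pd.DataFrame]:
    """Per-sample overlap counts; keep TUs with > `min_count_filter`
    fragments in at least `min_samples_filter` samples."""
    cfg = cfg or TUCallerConfig()
    samples = list(fragments_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    kept, rows = [], []
    for tu in tus:
        counts = {}
        for s in samples:
            key = (s, tu.interval.chrom, tu.interval.strand)
            if key not in cache:
                cache[key] = _frag_arrays(
                    fragments_by_sample[s], tu.interval.chrom, tu.interval.strand
                )
            counts[s] = _count_overlapping(tu, *cache[key])
        n_pass = sum(c > cfg.min_count_filter for c in counts.values())
        if n_pass >= cfg.min_samples_filter:
            kept.append(replace(tu, fragment_counts=counts))
            rows.append([tu.interval.name] + [counts[s] for s in samples])
    df = pd.DataFrame(rows, columns=["tu_id"] + samples).set_index("tu_id") if rows else (
        pd.DataFrame(columns=samples)
    )
    return kept, df


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

def call_tus(
    frag_df: pd.DataFrame,
    genes: Sequence[GenomicInterval],
    chrom_length: int,
    cfg: TUCallerConfig | None = None,
    decode: str = "posterior",
) -> tuple[list[TranscribedUnit], pd.DataFrame]:
    """Full pipeline on a fragment table (columns chrom/start/end/strand/sample).

    The HMM is fit once per strand on pooled genome-wide bins (default),
    then decoded per chromosome.
    """
    from .io_core import bin_fragment_midpoints
    from .synthetic import coverage_from_fragments

    cfg = cfg or TUCallerConfig()
    chroms = sorted(frag_df["chrom"].unique())
    all_tus: list[TranscribedUnit] = []
    frag_ivs = [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in frag_df[["chrom", "start", "end", "strand"]].itertuples(index=False)
    ]
    for strand in "+-":
        per_chrom_counts = {}
        for chrom in chroms:
            sel = frag_df[(frag_df["chrom"] == chrom) & (frag_df["strand"] == strand)]
            ivs = [
                GenomicInterval(chrom, int(s), int(e), strand)
                for s, e in sel[["start", "end"]].itertuples(index=False)
            ]
            counts, _ = bin_fragment_midpoints(ivs, cfg.bin_size, chrom_length)
            per_chrom_counts[chrom] = counts
        pooled = np.concatenate(list(per_chrom_counts.values()))
        params, _ = fit_hmm(pooled, cfg=cfg)
        for chrom in chroms:
            labels = decode_states(params, per_chrom_counts[chrom], method=decode)
            tus = states_to_putative_tus(labels, chrom, strand, cfg)
            tus = filter_putative_tus(tus, frag_ivs, cfg)
            cov = coverage_from_fragments(frag_df, chrom, strand, chrom_length)
            tus = [refine_boundaries(tu, cov, cfg) for tu in tus]
            tus = associate_tus_genes(tus, genes, cfg)
            tus = [
                child
                for tu in tus
                for child in split_tus_at_internal_tss(tu, genes, cov, cfg)
            ]
            all_tus.extend(tus)
    by_sample = {
        s: [
            GenomicInterval(c, int(a), int(b), st)
            for c, a, b, st in grp[["chrom", "start", "end", "strand"]].itertuples(index=False)
        ]
        for s, grp in frag_df.groupby("sample")
    }
    kept, counts = count_and_filter_tus(all_tus, by_sample, cfg)
    return kept, counts
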