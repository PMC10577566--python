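"""PWM motif scanning and covariate-adjusted enrichment.

Position frequency matrices (JASPAR text format) are converted to log-odds
score matrices against a background base composition. The presence
threshold is calibrated from the exact null score distribution (dynamic
programming over discretized scores) at a per-position match probability
of 5e-5. Scanning covers every window on both strands; N scores as
background (zero log-odds). Enrichment of a motif in a peak set is the
peak-set-membership coefficient of a logistic regression of presence on
membership, GC fraction and total motif content, with a Wald test and BH
correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "PWM",
    "EnrichmentResult",
    "read_jaspar",
    "scan_pwm",
    "scan_pwm_set",
    "enrichment_regression",
    "bh_adjust",
    "running_motif_enrichment",
    "running_overlap_fraction",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_MATCH_P = 5e-5


@dataclass
class PWM:
    id: str
    matrix: np.ndarray  # 4 x w position frequencies (counts or probabilities)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        col = self.matrix + self.pseudocount * self.background[:, None]
        return col / col.sum(axis=0)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in np.argmax(self.matrix, axis=0))

    def score_threshold(self, match_p: float = DEFAULT_MATCH_P, precision: int = 200) -> float:
        """Score cutoff with null match probability `match_p` per window.

        Exact null score distribution by DP: log-odds scores are
        discretized to a grid and convolved column by column under the
        background model; the threshold is the smallest grid score whose
        upper tail probability is <= match_p.
        """
        lo = self.log_odds
        span = lo.max() - lo.min()
        scale = precision / max(span, 1e-9)
        q = np.round((lo - lo.min()) * scale).astype(int)
        dist = np.array([1.0])
        offset = 0
        for j in range(self.width):
            col = np.zeros(q[:, j].max() + 1)
            for b in range(4):
                col[q[b, j]] += self.background[b]
            dist = np.convolve(dist, col)
        tail = np.cumsum(dist[::-1])[::-1]
        idx = np.flatnonzero(tail <= match_p)
        # short/sharp motifs may not reach match_p; fall back to the top of
        # the achievable score range (consensus-only matching)
        grid_cut = idx[0] if idx.size else dist.size - 1
        return float(grid_cut / scale + self.width * lo.min())


def read_jaspar(path: str | Path) -> list[PWM]:
    """Parse JASPAR text PFMs: '>ID NAME' then four 'A [ 1 2 ... ]' rows."""
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None and len(rows) == 4:
                    pwms.append(
                        PWM(current_id, np.array([rows[b] for b in "ACGT"]))
                    )
                current_id = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                nums = line[1:].strip().strip("[]").split()
                rows[base] = [float(x) for x in nums]
    if current_id is not None and len(rows) == 4:
        pwms.append(PWM(current_id, np.array([rows[b] for b in "ACGT"])))
    return pwms


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (incl. N) -> 4."""
    arr = np.full(len(seq), 4, dtype=int)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Max-per-window scores for one strand; N contributes 0 (background)."""
    w = log_odds.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0)
    padded = np.vstack([log_odds, np.zeros(log_odds.shape[1])])  # row 4 = N
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[codes[j : j + n], j]
    return scores


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


def scan_pwm(
    sequences: Sequence[tuple[str, str]],
    pwm: PWM,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Presence call per sequence: any window on either strand at or above
    the score threshold. Sequences shorter than the motif are absent."""
    if threshold is None:
        threshold = pwm.score_threshold()
    lo = pwm.log_odds
    rows = []
    for name, seq in sequences:
        codes = _encode(seq)
        fwd = _window_scores(codes, lo)
        rev = _window_scores(_revcomp_codes(codes), lo)
        present = bool(
            (fwd.size and fwd.max() >= threshold)
            or (rev.size and rev.max() >= threshold)
        )
        n_hits = int((fwd >= threshold).sum() + (rev >= threshold).sum())
        gc = float(np.isin(codes, [1, 2]).mean()) if codes.size else 0.0
        rows.append((name, present, n_hits, gc))
    return pd.DataFrame(
        rows, columns=["seq_id", "present", "n_hits", "gc"]
    ).set_index("seq_id")


def scan_pwm_set(
    sequences: Sequence[tuple[str, str]], pwms: Sequence[PWM]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Presence and hit-count matrices (sequence x motif) plus per-sequence
    covariates (GC fraction, total motif hits across the PWM set).

    For small PWM sets the enrichment covariate should exclude the tested
    motif's own hits (see `total_motifs_excluding`); with hundreds of PWMs
    the distinction is negligible.
    """
    presence, hits = {}, {}
    gc = None
    for pwm in pwms:
        res = scan_pwm(sequences, pwm)
        presence[pwm.id] = res["present"]
        hits[pwm.id] = res["n_hits"]
        gc = res["gc"]
    pres_df = pd.DataFrame(presence)
    hits_df = pd.DataFrame(hits)
    covars = pd.DataFrame({"gc": gc, "total_motifs": hits_df.sum(axis=1)})
    return pres_df, hits_df, covars


def total_motifs_excluding(hits: pd.DataFrame, motif_id: str) -> pd.Series:
    """Total hit count over the PWM set leaving out one motif's own hits."""
    return hits.drop(columns=[motif_id]).sum(axis=1)


@dataclass
class EnrichmentResult:
    motif_id: str
    log_odds_ratio: float
    std_error: float
    wald_p: float
    separation_flagged: bool = False
    fdr: float = np.nan


def enrichment_regression(
    presence: np.ndarray,
    membership: np.ndarray,
    gc: np.ndarray,
    total_motifs: np.ndarray,
    motif_id: str = "",
) -> EnrichmentResult:
    """Membership log-odds-ratio from presence ~ membership + gc + totals.

    Perfect separation falls back to a weakly ridge-penalized fit and is
    flagged in the result.
    """
    presence = np.asarray(presence, dtype=float)
    membership = np.asarray(membership, dtype=float)
    if len(np.unique(membership)) < 2:
        raise ValueError("both membership groups must be nonempty")
    if len(np.unique(presence)) < 2:
        raise ValueError("presence is constant")
    covariates = [
        c for c in (np.asarray(gc, float), np.asarray(total_motifs, float))
        if np.ptp(c) > 0  # constant covariates are collinear with the intercept
    ]
    X = sm.add_constant(np.column_stack([membership] + covariates))
    flagged = False
    try:
        fit = sm.Logit(presence, X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
            raise np.linalg.LinAlgError
        beta, se = fit.params[1], fit.bse[1]
    except Exception:  # noqa: BLE001 - separation / non-convergence
        flagged = True
        fit = sm.Logit(presence, X).fit_regularized(
            alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
        )
        beta = fit.params[1]
        se = np.nan
    wald_p = float(2 * norm.sf(abs(beta / se))) if np.isfinite(se) and se > 0 else np.nan
    return EnrichmentResult(
        motif_id=motif_id,
        log_odds_ratio=float(beta),
        std_error=float(se),
        wald_p=wald_p,
        separation_flagged=flagged,
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    out = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(n)
    result[order] = np.clip(out, 0, 1)
    return result


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window truncated identically at both edges."""
    x = np.asarray(x, dtype=float)
    n = x.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def running_motif_enrichment(
    presence_sorted: np.ndarray,
    baseline_fraction: float,
    window: int = 400,
) -> np.ndarray:
    """Fold-change of a centered running presence fraction over the
    background (non-DAR) presence fraction, along a T50-sorted peak rank."""
    if baseline_fraction <= 0:
        raise ValueError(
            "baseline fraction is 0; use a pseudo-fraction (e.g. 0.5/n) instead"
        )
    return _running_mean(presence_sorted, window) / baseline_fraction


def running_overlap_fraction(
    peaks_sorted: Sequence, reference_sets: dict[str, Sequence], window: int = 1000
) -> pd.DataFrame:
    """Per rank, fraction of a centered `window`-peak window overlapping at
    least one reference interval, per reference set."""
    out = {}
    for name, ref in reference_sets.items():
        by_chrom: dict[str, list] = {}
        for iv in ref:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c in by_chrom:
            by_chrom[c].sort()
        hits = np.zeros(len(peaks_sorted))
        for i, p in enumerate(peaks_sorted):
            for s, e in by_chrom.get(p.chrom, []):
                if s < p.end and p.start < e:
                    hits[i] = 1.0
                    break
                if s >= p.end:
                    break
            else:
                pass
        out[name] = _running_mean(hits, window)
    return pd.DataFrame(out)
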