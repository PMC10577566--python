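"""Ground-truth-annotated synthetic inputs for the depletion-time-course
pipeline.

The generators emulate the statistical structure of an acute pioneer-factor
depletion experiment: open-chromatin peaks whose library-size-normalized
accessibility follows log-logistic decay (down-DARs) or rise (up-DARs)
curves with known T50; stranded nascent-RNA fragments with planted
transcribed units; a generative link in which a gene's downregulation
probability is a logistic function of the Cauchy-kernel-weighted sum of
nearby lost-accessibility peaks; and peak DNA sequences with a motif
planted at elevated odds in the down-DAR class.

Every generator is a pure function of (config, seed): a fixed global seed
feeds an independent, named substream per generator, so stages can be rerun
independently and reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import CountMatrix, CoverageTrack, GenomicInterval

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_annotation",
    "simulate_peaks_and_timecourse",
    "simulate_deg_link",
    "simulate_ttseq_coverage",
    "simulate_sequences",
    "coverage_from_fragments",
]

# named substreams off the global seed; order is part of the contract
_STREAMS = {
    "annotation": 0,
    "peaks": 1,
    "timecourse": 2,
    "deg_link": 3,
    "ttseq": 4,
    "sequences": 5,
}

MIN_TSS_SPACING = 2_000  # bp


@dataclass
class SimConfig:
    """Study conditions for the synthetic depletion experiment.

    Defaults mirror the sampled design of an acute-depletion ATAC time
    course (untreated plus 30 min, 1, 2, 6, 24 h) with moderate sequencing
    depth and overdispersion. ``link_intercept``/``link_slope`` are
    calibrated once so that the oracle AUC of the generative
    accessibility-to-expression link is ~0.8.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 400
    n_peaks: int = 2_000
    frac_down_dar: float = 0.30
    frac_up_dar: float = 0.10
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 6.0, 24.0)
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    mean_depth: float = 100.0
    # generative accessibility -> expression link (Cauchy kernel, bp scale)
    link_kernel_scale: float = 20_000.0
    link_truncation: float = 5_000_000.0
    link_intercept: float = -3.5
    link_slope: float = 6.0e4
    # nascent-transcription rates, fragments per 200 bp bin
    tu_rate_high: float = 5.0
    tu_rate_low: float = 0.1
    tu_bin_size: int = 200
    tu_lognormal_sigma: float = 0.5
    fragment_length: float = 150.0
    # motif planting
    motif_odds: float = 3.0
    motif_base_rate: float = 0.15
    peak_width: int = 200
    # truth-parameter ranges for accessibility kinetics
    t50_range: tuple[float, float] = (0.25, 12.0)
    b_range: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        if not (0 <= self.frac_down_dar <= 1 and 0 <= self.frac_up_dar <= 1):
            raise ValueError("DAR fractions must lie in [0, 1]")
        if self.frac_down_dar + self.frac_up_dar > 1:
            raise ValueError("DAR fractions must sum to <= 1")
        tp = tuple(self.timepoints)
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing, starting at 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator, derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Per-peak, per-gene and per-sequence generative ground truth."""

    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    sequences: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> list[GenomicInterval]:
    """Place genes with TSSs at least 2 kb apart, random strands.

    Per chromosome, TSS positions are drawn by a stick-breaking scheme that
    enforces the minimum spacing exactly: sorted uniforms over the slack
    plus the cumulative spacing.
    """
    if cfg.n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = cfg.rng("annotation")
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    genes: list[GenomicInterval] = []
    margin = 25_000  # keep gene bodies clear of chromosome ends
    gi = 0
    for chrom, n in zip(cfg.chrom_names, per_chrom):
        usable = cfg.chrom_length - 2 * margin
        slack = usable - (n - 1) * MIN_TSS_SPACING
        if slack <= 0:
            raise ValueError(
                f"chrom_length {cfg.chrom_length} too small to place {n} genes "
                f"with {MIN_TSS_SPACING} bp TSS spacing"
            )
        u = np.sort(rng.uniform(0, slack, size=n))
        tss = (margin + u + np.arange(n) * MIN_TSS_SPACING).astype(int)
        lengths = rng.integers(2_000, 20_001, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for t, length, strand in zip(tss, lengths, strands):
            if strand == "+":
                start, end = t, min(t + length, cfg.chrom_length)
            else:
                start, end = max(0, t + 1 - length), t + 1
            genes.append(
                GenomicInterval(chrom, int(start), int(end), str(strand), f"g{gi:04d}")
            )
            gi += 1
    return genes


def gene_tss(gene: GenomicInterval) -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def sample_times(cfg: SimConfig) -> np.ndarray:
    """Per-sample hours for the time-course count matrix columns."""
    return np.repeat(np.asarray(cfg.timepoints, dtype=float), cfg.n_replicates)


# ---------------------------------------------------------------------------
# peaks + accessibility time course
# ---------------------------------------------------------------------------

def log_logistic(t: np.ndarray, A: float, K: float, B: float, T50: float, f: float = 1.0) -> np.ndarray:
    """A + (K - A) / (1 + (t/T50)^B)^f — finite at t = 0 (value K for B > 0)."""
    t = np.asarray(t, dtype=float)
    return A + (K - A) / (1.0 + (t / T50) ** B) ** f


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson limit)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_peaks_and_timecourse(
    cfg: SimConfig, genes: Sequence[GenomicInterval]
) -> tuple[list[GenomicInterval], CountMatrix, SyntheticTruth]:
    """Peaks with category-specific accessibility kinetics and NB counts.

    Down-DAR peaks are placed at Cauchy-distributed distances (scale 20 kb)
    from random gene TSSs so that genes with many nearby down-DARs become
    the downregulation candidates of the generative link; other peaks are
    uniform. Expected normalized counts follow
    depth * (A + (K - A)/(1 + (t/T50)^B)^f) with per-peak truth parameters.
    """
    rng_p = cfg.rng("peaks")
    rng_t = cfg.rng("timecourse")
    n_down = int(round(cfg.frac_down_dar * cfg.n_peaks))
    n_up = int(round(cfg.frac_up_dar * cfg.n_peaks))
    n_ndar = cfg.n_peaks - n_down - n_up
    categories = ["down_dar"] * n_down + ["up_dar"] * n_up + ["ndar"] * n_ndar

    tss = np.array([gene_tss(g) for g in genes])
    gene_chrom = np.array([g.chrom for g in genes])
    half = cfg.peak_width // 2
    lo, hi = half, cfg.chrom_length - half - 1

    chroms: list[str] = []
    summits: list[int] = []
    for cat in categories:
        if cat == "down_dar":
            gidx = rng_p.integers(0, len(genes))
            offset = rng_p.standard_cauchy() * cfg.link_kernel_scale
            pos = int(np.clip(tss[gidx] + offset, lo, hi))
            chroms.append(gene_chrom[gidx])
        else:
            chroms.append(cfg.chrom_names[rng_p.integers(0, cfg.n_chroms)])
            pos = int(rng_p.integers(lo, hi))
        summits.append(pos)

    peaks = [
        GenomicInterval(c, s - half, s + half, ".", f"p{i:05d}", summit=s)
        for i, (c, s) in enumerate(zip(chroms, summits))
    ]

    # truth kinetics
    t50 = np.exp(rng_p.uniform(np.log(cfg.t50_range[0]), np.log(cfg.t50_range[1]), cfg.n_peaks))
    bpar = rng_p.uniform(*cfg.b_range, cfg.n_peaks)
    A = np.zeros(cfg.n_peaks)
    K = np.ones(cfg.n_peaks)
    for i, cat in enumerate(categories):
        if cat == "up_dar":
            A[i], K[i] = 1.0, 0.2  # rises from 0.2 toward 1 over time
        elif cat == "ndar":
            A[i] = K[i] = 1.0
            t50[i] = np.nan
            bpar[i] = np.nan

    base_times = np.asarray(cfg.timepoints)
    times = np.repeat(base_times, cfg.n_replicates)
    sample_ids = [
        f"t{t:g}h_r{r + 1}" for t in base_times for r in range(cfg.n_replicates)
    ]
    lib = rng_t.uniform(0.8, 1.25, size=len(times))
    means = np.empty((cfg.n_peaks, len(times)))
    for i, cat in enumerate(categories):
        if cat == "ndar":
            curve = np.ones_like(times)
        else:
            curve = log_logistic(times, A[i], K[i], bpar[i], t50[i])
        means[i] = cfg.mean_depth * curve * lib
    counts = _nb_sample(rng_t, means, cfg.nb_dispersion)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=[p.name for p in peaks], columns=sample_ids)
    )
    truth = SyntheticTruth(
        peaks=pd.DataFrame(
            {
                "peak_id": [p.name for p in peaks],
                "chrom": chroms,
                "summit": summits,
                "category": categories,
                "A": A,
                "K": K,
                "B": bpar,
                "f": 1.0,
                "T50": t50,
            }
        ).set_index("peak_id"),
    )
    return peaks, cm, truth


# ---------------------------------------------------------------------------
# accessibility -> expression link
# ---------------------------------------------------------------------------

def _cauchy_weight(d: np.ndarray, scale: float, truncation: float) -> np.ndarray:
    w = 1.0 / (np.pi * scale * (1.0 + (d / scale) ** 2))
    return np.where(np.abs(d) <= truncation, w, 0.0)


def simulate_deg_link(
    cfg: SimConfig,
    genes: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Bernoulli downregulation labels from the Cauchy-weighted link.

    P(gene down) = logistic(intercept + slope * sum of truncated-Cauchy
    weights of down-DAR peaks near the TSS). Baseline (untreated) expression
    is independent lognormal, used downstream for expression matching.
    Appends a ``genes`` table to ``truth`` and returns it.
    """
    rng = cfg.rng("deg_link")
    cats = truth.peaks["category"].to_numpy()
    down_idx = np.flatnonzero(cats == "down_dar")
    down_chrom = truth.peaks["chrom"].to_numpy()[down_idx]
    down_summit = truth.peaks["summit"].to_numpy()[down_idx]

    rows = []
    for g in genes:
        t = gene_tss(g)
        on_chrom = down_summit[down_chrom == g.chrom]
        d = on_chrom.astype(float) - t
        s = _cauchy_weight(d, cfg.link_kernel_scale, cfg.link_truncation).sum()
        rows.append((g.name, g.chrom, t, g.strand, s))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "link_sum"])
    df["p_down"] = expit(cfg.link_intercept + cfg.link_slope * df["link_sum"])
    df["deg_status"] = np.where(rng.uniform(size=len(df)) < df["p_down"], "down", "stable")
    df["baseline_expr"] = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(df))
    df = df.set_index("gene_id")
    truth.genes = df
    return df


# ---------------------------------------------------------------------------
# nascent-transcription fragments
# ---------------------------------------------------------------------------

def simulate_ttseq_coverage(
    cfg: SimConfig,
    genes: Sequence[GenomicInterval],
    deg_labels: pd.DataFrame | None = None,
    timepoints: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Stranded nascent-RNA fragments with planted transcribed units.

    Fragment midpoints are Poisson-lognormal per 200 bp bin inside gene
    bodies (rate ``tu_rate_high``, scaled down over time for down-DEGs) and
    Poisson at ``tu_rate_low`` elsewhere on both strands. Returns a fragment
    table (chrom, start, end, strand, sample, source_gene).
    """
    rng = cfg.rng("ttseq")
    times = list(cfg.timepoints if timepoints is None else timepoints)
    bs = cfg.tu_bin_size
    sig = cfg.tu_lognormal_sigma
    down_genes = (
        set(deg_labels.index[deg_labels["deg_status"] == "down"])
        if deg_labels is not None
        else set()
    )
    frags: list[tuple[str, int, int, str, str, str]] = []

    def emit(
        chrom: str,
        n: int,
        bin_start: int,
        strand: str,
        sample: str,
        src: str,
        clip: tuple[int, int] | None = None,
    ) -> None:
        if n <= 0:
            return
        width = bs if clip is None else min(bs, clip[1] - bin_start)
        mids = rng.integers(bin_start, bin_start + width, size=n)
        lens = np.clip(rng.normal(cfg.fragment_length, 15.0, size=n), 50, None).astype(int)
        for m, L in zip(mids, lens):
            s = max(0, int(m) - L // 2)
            e = s + L
            if clip is not None:
                # nascent fragments come from within the transcript
                s, e = max(s, clip[0]), min(e, clip[1])
                if e - s < 20:
                    continue
            frags.append((chrom, s, e, strand, sample, src))

    for t in times:
        sample = f"t{t:g}h"
        decay = 1.0  # placeholder; per-gene below
        for g in genes:
            n_bins = max(1, -(-len(g) // bs))
            # per-bin lognormal rate, mean tu_rate_high
            rates = np.exp(rng.normal(np.log(cfg.tu_rate_high) - sig**2 / 2, sig, n_bins))
            if g.name in down_genes:
                decay = 0.15 + 0.85 / (1.0 + (t / 1.0) ** 2)
                rates = rates * decay
            counts = rng.poisson(rates)
            for b, n in enumerate(counts):
                emit(
                    g.chrom, int(n), g.start + b * bs, g.strand, sample, g.name,
                    clip=(g.start, g.end),
                )
        # background on both strands, genome-wide
        n_bg_bins = cfg.chrom_length // bs
        for chrom in cfg.chrom_names:
            for strand in "+-":
                if cfg.tu_rate_low <= 0:
                    continue
                total = rng.poisson(cfg.tu_rate_low * n_bg_bins)
                bins = rng.integers(0, n_bg_bins, size=total)
                for b in bins:
                    emit(chrom, 1, int(b) * bs, strand, sample, "")
    df = pd.DataFrame(
        frags, columns=["chrom", "start", "end", "strand", "sample", "source_gene"]
    )
    return df.sort_values(["chrom", "start", "end", "strand", "sample"], kind="stable").reset_index(
        drop=True
    )


def coverage_from_fragments(
    frag_df: pd.DataFrame, chrom: str, strand: str, chrom_length: int
) -> CoverageTrack:
    """Pooled per-bp fragment coverage for one chromosome and strand."""
    sel = frag_df[(frag_df["chrom"] == chrom) & (frag_df["strand"] == strand)]
    cov = np.zeros(chrom_length + 1, dtype=float)
    np.add.at(cov, np.clip(sel["start"].to_numpy(), 0, chrom_length), 1.0)
    np.add.at(cov, np.clip(sel["end"].to_numpy(), 0, chrom_length), -1.0)
    return CoverageTrack(chrom=chrom, values=np.cumsum(cov)[:chrom_length], strand=strand)


# ---------------------------------------------------------------------------
# peak sequences with planted motifs
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_sequences(
    cfg: SimConfig,
    peaks: Sequence[GenomicInterval],
    truth: SyntheticTruth,
    pwm_probs: np.ndarray,
) -> list[tuple[str, str]]:
    """Per-peak DNA with a motif planted at elevated odds in down-DARs.

    Background is iid with per-peak GC fraction (recorded as a covariate in
    ``truth.sequences``); the planted instance is sampled column-wise from
    the PWM probabilities, on a random strand at a random offset. The
    planting probability for non-down peaks is ``motif_base_rate``; for
    down-DARs the odds are multiplied by ``motif_odds``.
    """
    pwm_probs = np.asarray(pwm_probs, dtype=float)
    w = pwm_probs.shape[1]
    if w >= cfg.peak_width:
        raise ValueError("PWM width must be smaller than peak width")
    rng = cfg.rng("sequences")
    p0 = cfg.motif_base_rate
    odds0 = p0 / (1 - p0)
    p_down = (cfg.motif_odds * odds0) / (1 + cfg.motif_odds * odds0)
    cats = truth.peaks["category"]

    records: list[tuple[str, str]] = []
    planted_flags, gcs = [], []
    for p in peaks:
        gc = rng.uniform(0.3, 0.7)
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(4, size=len(p), p=probs)
        p_plant = p_down if cats.loc[p.name] == "down_dar" else p0
        planted = bool(rng.uniform() < p_plant)
        if planted:
            pos = int(rng.integers(0, len(p) - w + 1))
            # plant the consensus so presence is a faithful planting readout
            inst = np.argmax(pwm_probs, axis=0)
            if rng.uniform() < 0.5:
                inst = 3 - inst[::-1]  # reverse complement
            seq[pos : pos + w] = inst
        records.append((p.name, "".join(_BASES[seq])))
        planted_flags.append(planted)
        gcs.append(gc)
    truth.sequences = pd.DataFrame(
        {"peak_id": [p.name for p in peaks], "planted": planted_flags, "gc": gcs}
    ).set_index("peak_id")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
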