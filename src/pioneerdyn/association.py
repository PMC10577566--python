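"""Peak-to-gene association and kernel weighting.

Four association rules: a simple distance threshold from the TSS, a
basal-plus-extension regulatory domain (GREAT-style), and two k-nearest
neighbor rules (nearest genes per peak / nearest peaks per gene). Each
peak-gene pair carries a signed distance, summit minus TSS oriented by
gene strand (upstream negative). Kernel weighting replaces counting with
distance-decaying density weights (uniform / Laplace / Cauchy / Gaussian),
truncated at 5 Mb inside a 10 Mb candidate window; summing uniform-kernel
weights reduces exactly to the distance-threshold count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import GenomicInterval

__all__ = [
    "AssociationRule",
    "KernelSpec",
    "associate",
    "kernel_weight",
    "weighted_sums_per_gene",
    "tss_peak_density",
    "parameter_sweep",
]


@dataclass
class AssociationRule:
    rule: str  # distance_threshold | basal_extension | knn_genes_per_peak | knn_peaks_per_gene
    distance: int = 25_000
    k: int = 6
    basal_up: int = 5_000
    basal_down: int = 1_000
    extension_cap: int = 1_000_000


@dataclass
class KernelSpec:
    family: str = "cauchy"  # uniform | laplace | cauchy | gaussian
    scale: float = 20_000.0
    truncation: float = 5_000_000.0
    window: float = 10_000_000.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.truncation > self.window / 2:
            raise ValueError("truncation must be <= window/2")


def _tss(gene: GenomicInterval) -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def signed_distance(peak: GenomicInterval, gene: GenomicInterval) -> int:
    """Summit (or midpoint) minus TSS, oriented so upstream is negative."""
    d = peak.anchor - _tss(gene)
    return d if gene.strand != "-" else -d


def associate(
    rule: AssociationRule,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Peak-gene pairs with signed distances under one association rule.

    Pairing is per chromosome. Returns columns peak_id, gene_id, distance.
    """
    rows: list[tuple[str, str, int]] = []
    by_chrom_genes: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
    by_chrom_peaks: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom_peaks.setdefault(p.chrom, []).append(p)

    if rule.rule == "distance_threshold":
        for chrom, ps in by_chrom_peaks.items():
            for p in ps:
                for g in by_chrom_genes.get(chrom, []):
                    d = signed_distance(p, g)
                    if abs(d) <= rule.distance:
                        rows.append((p.name, g.name, d))
    elif rule.rule == "basal_extension":
        domains = _regulatory_domains(genes, rule)
        for chrom, ps in by_chrom_peaks.items():
            for p in ps:
                pos = p.anchor
                for g in by_chrom_genes.get(chrom, []):
                    lo, hi = domains[g.name]
                    if lo <= pos < hi:
                        rows.append((p.name, g.name, signed_distance(p, g)))
    elif rule.rule == "knn_genes_per_peak":
        for chrom, ps in by_chrom_peaks.items():
            gs = by_chrom_genes.get(chrom, [])
            if not gs:
                continue
            tss = np.array([_tss(g) for g in gs])
            for p in ps:
                order = np.argsort(np.abs(tss - p.anchor), kind="stable")[: rule.k]
                for i in order:
                    rows.append((p.name, gs[i].name, signed_distance(p, gs[i])))
    elif rule.rule == "knn_peaks_per_gene":
        for chrom, gs in by_chrom_genes.items():
            ps = by_chrom_peaks.get(chrom, [])
            if not ps:
                continue
            anchors = np.array([p.anchor for p in ps])
            for g in gs:
                order = np.argsort(np.abs(anchors - _tss(g)), kind="stable")[: rule.k]
                for i in order:
                    rows.append((ps[i].name, g.name, signed_distance(ps[i], g)))
    else:
        raise ValueError(f"unknown association rule {rule.rule!r}")
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])


def _regulatory_domains(
    genes: Sequence[GenomicInterval], rule: AssociationRule
) -> dict[str, tuple[int, int]]:
    """Basal domain (strand-oriented up/down of the TSS) plus extension up
    to `extension_cap`, stopping at the nearest neighboring basal domain."""
    basal: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        t = _tss(g)
        if g.strand == "-":
            lo, hi = t - rule.basal_down + 1, t + rule.basal_up + 1
        else:
            lo, hi = t - rule.basal_up, t + rule.basal_down
        basal[g.name] = (g.chrom, lo, hi)
    domains: dict[str, tuple[int, int]] = {}
    for g in genes:
        chrom, lo, hi = basal[g.name]
        ext_lo = lo - rule.extension_cap
        ext_hi = hi + rule.extension_cap
        for other, (c2, lo2, hi2) in basal.items():
            if other == g.name or c2 != chrom:
                continue
            if hi2 <= lo:  # neighbor basal domain to the left
                ext_lo = max(ext_lo, hi2)
            if lo2 >= hi:  # to the right
                ext_hi = min(ext_hi, lo2)
        domains[g.name] = (ext_lo, ext_hi)
    return domains


def kernel_weight(distance, spec: KernelSpec):
    """Distance-decaying kernel weight; exactly 0 beyond the truncation."""
    d = np.abs(np.asarray(distance, dtype=float))
    s = spec.scale
    if spec.family == "uniform":
        w = (d <= s).astype(float)
    elif spec.family == "laplace":
        w = np.exp(-d / s) / (2 * s)
    elif spec.family == "cauchy":
        w = 1.0 / (np.pi * s * (1.0 + (d / s) ** 2))
    elif spec.family == "gaussian":
        w = np.exp(-0.5 * (d / s) ** 2) / (s * np.sqrt(2 * np.pi))
    else:
        raise ValueError(f"unknown kernel family {spec.family!r}")
    return np.where(d <= spec.truncation, w, 0.0)


def weighted_sums_per_gene(
    peaks: Sequence[GenomicInterval],
    categories: pd.Series,
    genes: Sequence[GenomicInterval],
    spec: KernelSpec,
) -> pd.DataFrame:
    """Per-gene, per-category sums of kernel weights over peaks in the
    candidate window (half-window each side of the TSS)."""
    cat_values = sorted(categories.unique())
    cat_index = {c: j for j, c in enumerate(cat_values)}
    half_window = spec.window / 2
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = [p for p in peaks if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.anchor for p in ps], dtype=float),
            np.array([cat_index[categories.loc[p.name]] for p in ps]),
        )
    sums = np.zeros((len(genes), len(cat_values)))
    for i, g in enumerate(genes):
        if g.chrom not in by_chrom:
            continue
        anchors, cats = by_chrom[g.chrom]
        d = anchors - _tss(g)
        in_window = np.abs(d) <= half_window
        w = kernel_weight(d[in_window], spec)
        np.add.at(sums[i], cats[in_window], w)
    out = pd.DataFrame(sums, index=[g.name for g in genes], columns=cat_values)
    out.index.name = "gene_id"
    return out


def tss_peak_density(
    gene_sets: dict[str, Sequence[GenomicInterval]],
    peak_sets: dict[str, Sequence[GenomicInterval]],
    bin_size: int = 10_000,
    span: int = 100_000,
) -> pd.DataFrame:
    """Per gene-set x peak-set counts of peak summits in signed bins around
    the TSS, normalized per gene. Distances are strand-oriented."""
    edges = np.arange(-span, span + bin_size, bin_size)
    centers = (edges[:-1] + edges[1:]) / 2
    rows = []
    for gname, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"empty gene set {gname!r}")
        for pname, peaks in peak_sets.items():
            hist = np.zeros(centers.size)
            for g in genes:
                t = _tss(g)
                for p in peaks:
                    if p.chrom != g.chrom:
                        continue
                    d = signed_distance(p, g)
                    if -span <= d < span:
                        hist[int((d + span) // bin_size)] += 1
            hist = hist / len(genes)
            for c, h in zip(centers, hist):
                rows.append((gname, pname, int(c), h))
    return pd.DataFrame(rows, columns=["gene_set", "peak_set", "distance", "density"])


def parameter_sweep(
    grid: Sequence,
    feature_builder: Callable[[object], pd.DataFrame],
    outcome: pd.Series,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[object, pd.DataFrame]:
    """Choose the association/kernel parameter minimizing CV deviance.

    For every grid point, `feature_builder` produces a gene-by-category
    feature table; a lasso-logistic model is fit and scored by k-fold CV
    binomial deviance. Ties go to the earlier (simpler/smaller) grid point.
    """
    from .prediction import cv_deviance

    if len(grid) == 0:
        raise ValueError("empty grid")
    if outcome.nunique() < 2:
        raise ValueError("outcome is single-class")
    rows = []
    for point in grid:
        X = feature_builder(point)
        X = X.loc[outcome.index]
        dev = cv_deviance(X.to_numpy(float), outcome.to_numpy(int), cv_folds, seed)
        rows.append((point, dev))
    curve = pd.DataFrame(rows, columns=["param", "cv_deviance"])
    best = curve["param"].iloc[int(np.argmin(curve["cv_deviance"].to_numpy()))]
    return best, curve
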