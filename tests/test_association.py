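import numpy as np
import pandas as pd
import pytest

from pioneerdyn import association as assoc
from pioneerdyn.io_core import GenomicInterval


def _random_fixture(rng, n_peaks=50, n_genes=10, span=2_000_000):
    genes = []
    for i in range(n_genes):
        s = int(rng.integers(10_000, span - 30_000))
        strand = "+" if rng.uniform() < 0.5 else "-"
        genes.append(GenomicInterval("chr1", s, s + 20_000, strand, f"g{i}"))
    peaks = []
    for i in range(n_peaks):
        s = int(rng.integers(100, span - 300))
        peaks.append(GenomicInterval("chr1", s, s + 200, ".", f"p{i}", summit=s + 100))
    return peaks, genes


def _brute_force(rule, peaks, genes):
    """Quadratic-scan reference for all four association rules."""
    pairs = set()
    tss = {g.name: (g.start if g.strand == "+" else g.end - 1) for g in genes}
    if rule.rule == "distance_threshold":
        for p in peaks:
            for g in genes:
                if abs(p.anchor - tss[g.name]) <= rule.distance:
                    pairs.add((p.name, g.name))
    elif rule.rule == "knn_genes_per_peak":
        for p in peaks:
            dist = sorted(genes, key=lambda g: abs(tss[g.name] - p.anchor))
            for g in dist[: rule.k]:
                pairs.add((p.name, g.name))
    elif rule.rule == "knn_peaks_per_gene":
        for g in genes:
            dist = sorted(peaks, key=lambda p: abs(p.anchor - tss[g.name]))
            for p in dist[: rule.k]:
                pairs.add((p.name, g.name))
    elif rule.rule == "basal_extension":
        basal = {}
        for g in genes:
            t = tss[g.name]
            if g.strand == "-":
                basal[g.name] = (t - rule.basal_down + 1, t + rule.basal_up + 1)
            else:
                basal[g.name] = (t - rule.basal_up, t + rule.basal_down)
        for g in genes:
            lo, hi = basal[g.name]
            ext_lo, ext_hi = lo - rule.extension_cap, hi + rule.extension_cap
            for other, (lo2, hi2) in basal.items():
                if other == g.name:
                    continue
                if hi2 <= lo:
                    ext_lo = max(ext_lo, hi2)
                if lo2 >= hi:
                    ext_hi = min(ext_hi, lo2)
            for p in peaks:
                if ext_lo <= p.anchor < ext_hi:
                    pairs.add((p.name, g.name))
    return pairs


class TestAssociate:
    def test_distance_threshold_default(self):
        g = GenomicInterval("chr1", 100_000, 120_000, "+", "g0")
        near = GenomicInterval("chr1", 109_900, 110_100, ".", "near", summit=110_000)
        far = GenomicInterval("chr1", 129_900, 130_100, ".", "far", summit=130_000)
        out = assoc.associate(assoc.AssociationRule("distance_threshold"), [near, far], [g])
        assert set(out.peak_id) == {"near"}
        assert out.distance.iloc[0] == 10_000

    def test_knn_single_nearest(self):
        g1 = GenomicInterval("chr1", 100_000, 104_000, "+", "gA")  # TSS 5 kb away
        g2 = GenomicInterval("chr1", 112_000, 117_000, "+", "gB")  # TSS 7 kb away
        p = GenomicInterval("chr1", 104_900, 105_100, ".", "p", summit=105_000)
        out = assoc.associate(
            assoc.AssociationRule("knn_genes_per_peak", k=1), [p], [g1, g2]
        )
        assert out.gene_id.tolist() == ["gA"]

    @pytest.mark.parametrize(
        "rule_name", ["distance_threshold", "basal_extension",
                      "knn_genes_per_peak", "knn_peaks_per_gene"],
    )
    def test_matches_brute_force(self, rule_name, rng):
        peaks, genes = _random_fixture(rng)
        rule = assoc.AssociationRule(rule_name, distance=100_000, k=3,
                                     extension_cap=150_000)
        got = assoc.associate(rule, peaks, genes)
        assert set(zip(got.peak_id, got.gene_id)) == _brute_force(rule, peaks, genes)

    def test_unknown_rule_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            assoc.associate(assoc.AssociationRule("nearest_cousin"), [], [])

    def test_shift_invariance(self, rng):
        peaks, genes = _random_fixture(rng, n_peaks=20, n_genes=5)
        rule = assoc.AssociationRule("distance_threshold", distance=50_000)
        base = assoc.associate(rule, peaks, genes)
        shift = 123_456
        peaks2 = [
            GenomicInterval(p.chrom, p.start + shift, p.end + shift, p.strand,
                            p.name, p.summit + shift)
            for p in peaks
        ]
        genes2 = [
            GenomicInterval(g.chrom, g.start + shift, g.end + shift, g.strand, g.name)
            for g in genes
        ]
        shifted = assoc.associate(rule, peaks2, genes2)
        pd.testing.assert_frame_equal(base, shifted)


class TestKernels:
    def test_cauchy_at_zero(self):
        spec = assoc.KernelSpec(family="cauchy", scale=20_000)
        assert assoc.kernel_weight(0, spec) == pytest.approx(1 / (np.pi * 20_000))

    @pytest.mark.parametrize("family", ["uniform", "laplace", "cauchy", "gaussian"])
    def test_truncation_and_symmetry(self, family):
        spec = assoc.KernelSpec(family=family, scale=20_000)
        assert assoc.kernel_weight(6_000_000, spec) == 0.0
        d = np.array([-30_000, 30_000])
        w = assoc.kernel_weight(d, spec)
        assert w[0] == w[1]

    @pytest.mark.parametrize("family", ["uniform", "laplace", "cauchy", "gaussian"])
    def test_nonincreasing_in_distance(self, family):
        spec = assoc.KernelSpec(family=family, scale=10_000)
        d = np.linspace(0, spec.truncation, 1000)
        w = assoc.kernel_weight(d, spec)
        assert np.all(np.diff(w) <= 1e-18)

    def test_uniform_sum_equals_threshold_count(self, rng):
        """Summing uniform-kernel weights is exactly counting peaks within
        the distance threshold."""
        peaks, genes = _random_fixture(rng, n_peaks=100, n_genes=12)
        d = 25_000
        spec = assoc.KernelSpec(family="uniform", scale=d)
        cats = pd.Series("all", index=[p.name for p in peaks])
        sums = assoc.weighted_sums_per_gene(peaks, cats, genes, spec)
        counts = (
            assoc.associate(assoc.AssociationRule("distance_threshold", distance=d),
                            peaks, genes)
            .groupby("gene_id").size()
        )
        for g in genes:
            assert sums.loc[g.name, "all"] == counts.get(g.name, 0)


class TestWeightedSums:
    def test_no_peaks_all_zero(self):
        g = GenomicInterval("chr1", 10_000, 20_000, "+", "g0")
        out = assoc.weighted_sums_per_gene(
            [], pd.Series(dtype=object), [g], assoc.KernelSpec()
        )
        assert out.shape == (1, 0)

    def test_single_peak_at_tss(self):
        g = GenomicInterval("chr1", 10_000, 20_000, "+", "g0")
        p = GenomicInterval("chr1", 9_900, 10_100, ".", "p0", summit=10_000)
        spec = assoc.KernelSpec()
        out = assoc.weighted_sums_per_gene([p], pd.Series({"p0": "down_dar"}), [g], spec)
        assert out.loc["g0", "down_dar"] == pytest.approx(
            float(assoc.kernel_weight(0, spec))
        )

    def test_matches_double_loop_oracle(self, rng):
        peaks, genes = _random_fixture(rng, n_peaks=200, n_genes=20)
        cats = pd.Series(
            rng.choice(["down_dar", "ndar", "up_dar"], size=len(peaks)),
            index=[p.name for p in peaks],
        )
        spec = assoc.KernelSpec(family="laplace", scale=30_000)
        got = assoc.weighted_sums_per_gene(peaks, cats, genes, spec)
        for g in genes:
            t = g.start if g.strand == "+" else g.end - 1
            for cat in got.columns:
                expected = 0.0
                for p in peaks:
                    if cats[p.name] != cat or abs(p.anchor - t) > spec.window / 2:
                        continue
                    expected += float(assoc.kernel_weight(p.anchor - t, spec))
                assert got.loc[g.name, cat] == pytest.approx(expected, abs=1e-12)


class TestDensityAndSweep:
    def test_empty_peak_set_zero_density(self):
        g = GenomicInterval("chr1", 50_000, 60_000, "+", "g0")
        out = assoc.tss_peak_density({"genes": [g]}, {"peaks": []})
        assert (out["density"] == 0).all()

    def test_peaks_at_tss_concentrate_centrally(self):
        genes = [GenomicInterval("chr1", 50_000, 60_000, "+", "g0")]
        peaks = [GenomicInterval("chr1", 49_900, 50_100, ".", "p0", summit=50_000)]
        out = assoc.tss_peak_density({"g": genes}, {"p": peaks})
        nz = out[out.density > 0]
        assert len(nz) == 1 and abs(nz.distance.iloc[0]) <= 5_000

    def test_density_matches_hand_binned_histogram(self, rng):
        peaks, genes = _random_fixture(rng, n_peaks=30, n_genes=4)
        out = assoc.tss_peak_density({"g": genes}, {"p": peaks}, span=200_000)
        # total mass equals the number of in-span peak-gene pairs
        total = out.density.sum() * len(genes)
        expected = 0
        for g in genes:
            t = g.start if g.strand == "+" else g.end - 1
            for p in peaks:
                d = (p.anchor - t) * (1 if g.strand == "+" else -1)
                if -200_000 <= d < 200_000:
                    expected += 1
        assert total == pytest.approx(expected)

    def test_single_point_grid_returned(self, sim_bundle):
        labels = sim_bundle["labels"]
        truth = sim_bundle["truth"]
        peaks, genes = sim_bundle["peaks"], sim_bundle["genes"]
        y = (labels["deg_status"] == "down").astype(int)

        def build(scale):
            return assoc.weighted_sums_per_gene(
                peaks, truth.peaks["category"], genes,
                assoc.KernelSpec(scale=scale),
            )

        best, curve = assoc.parameter_sweep([20_000], build, y, cv_folds=3)
        assert best == 20_000 and len(curve) == 1

    def test_sweep_determinism(self, sim_bundle):
        labels = sim_bundle["labels"]
        truth = sim_bundle["truth"]
        peaks, genes = sim_bundle["peaks"], sim_bundle["genes"]
        y = (labels["deg_status"] == "down").astype(int)

        def build(scale):
            return assoc.weighted_sums_per_gene(
                peaks, truth.peaks["category"], genes, assoc.KernelSpec(scale=scale)
            )

        _, c1 = assoc.parameter_sweep([5_000, 20_000], build, y, cv_folds=3, seed=4)
        _, c2 = assoc.parameter_sweep([5_000, 20_000], build, y, cv_folds=3, seed=4)
        pd.testing.assert_frame_equal(c1, c2)
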