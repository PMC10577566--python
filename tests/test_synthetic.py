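import numpy as np
import pandas as pd
import pytest

from pioneerdyn import synthetic as syn
from pioneerdyn.io_core import estimate_size_factors


class TestConfig:
    def test_rejects_bad_fractions_and_times(self):
        with pytest.raises(ValueError):
            syn.SimConfig(frac_down_dar=0.8, frac_up_dar=0.4)
        with pytest.raises(ValueError):
            syn.SimConfig(timepoints=(0.5, 1.0))
        with pytest.raises(ValueError):
            syn.SimConfig(timepoints=(0.0, 2.0, 1.0))


class TestAnnotation:
    def test_deterministic(self, cfg):
        assert syn.simulate_annotation(cfg) == syn.simulate_annotation(cfg)

    def test_min_tss_spacing_bruteforce(self):
        cfg = syn.SimConfig(seed=3, n_chroms=2, chrom_length=3_000_000, n_genes=500)
        genes = syn.simulate_annotation(cfg)
        assert len(genes) == 500
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(syn.gene_tss(g))
        for tss in by_chrom.values():
            tss = sorted(tss)
            assert min(b - a for a, b in zip(tss, tss[1:])) >= syn.MIN_TSS_SPACING

    def test_too_small_chromosome_errors(self):
        with pytest.raises(ValueError, match="too small"):
            syn.simulate_annotation(
                syn.SimConfig(n_chroms=1, chrom_length=60_000, n_genes=50)
            )

    def test_two_genes_small_genome(self):
        cfg = syn.SimConfig(n_chroms=1, chrom_length=100_000, n_genes=2)
        genes = syn.simulate_annotation(cfg)
        t = sorted(syn.gene_tss(g) for g in genes)
        assert t[1] - t[0] >= syn.MIN_TSS_SPACING


class TestTimecourse:
    def test_deterministic(self, cfg):
        genes = syn.simulate_annotation(cfg)
        _, cm1, _ = syn.simulate_peaks_and_timecourse(cfg, genes)
        _, cm2, _ = syn.simulate_peaks_and_timecourse(cfg, genes)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_no_dars_means_constant_trajectories(self):
        cfg = syn.SimConfig(seed=2, frac_down_dar=0.0, frac_up_dar=0.0, n_peaks=50)
        genes = syn.simulate_annotation(cfg)
        _, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        assert (truth.peaks["category"] == "ndar").all()
        assert truth.peaks["T50"].isna().all()

    def test_poisson_limit_mean_recovery(self):
        """At tiny dispersion and high depth, sample means at t=0 approach
        depth for stable peaks (law of large numbers)."""
        cfg = syn.SimConfig(
            seed=4, n_peaks=500, frac_down_dar=0.0, frac_up_dar=0.0,
            nb_dispersion=0.0, mean_depth=1e6, n_replicates=1,
        )
        genes = syn.simulate_annotation(cfg)
        _, cm, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        sf = estimate_size_factors(cm)
        norm = sf.normalized()
        # normalization removes the library factors: per-sample means of the
        # constant peaks agree to <1%; the absolute level matches the depth
        # up to the unscaled size-factor convention (geometric-mean gauge)
        sample_means = norm.mean(axis=0)
        assert (abs(sample_means / sample_means.mean() - 1) < 0.01).all()
        assert abs(sample_means.mean() / 1e6 - 1) < 0.2

    def test_truth_invariants(self, sim_bundle):
        tp = sim_bundle["truth"].peaks
        down = tp[tp.category == "down_dar"]
        assert (down["K"] > down["A"]).all()
        assert np.isfinite(down["T50"]).all()
        ndar = tp[tp.category == "ndar"]
        assert (ndar["A"] == ndar["K"]).all()


class TestDegLink:
    def test_zero_slope_constant_probability(self):
        cfg = syn.SimConfig(seed=5, link_slope=0.0)
        genes = syn.simulate_annotation(cfg)
        peaks, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        lab = syn.simulate_deg_link(cfg, genes, peaks, truth)
        expected = 1 / (1 + np.exp(-cfg.link_intercept))
        assert np.allclose(lab["p_down"], expected)

    def test_gene_without_nearby_peaks_gets_zero_sum(self):
        cfg = syn.SimConfig(seed=6, frac_down_dar=0.0, frac_up_dar=0.0)
        genes = syn.simulate_annotation(cfg)
        peaks, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        lab = syn.simulate_deg_link(cfg, genes, peaks, truth)
        assert (lab["link_sum"] == 0).all()

    def test_empirical_rate_matches_probabilities(self):
        """Binomial check: realized down fraction within 3 SE of the mean
        generated probability."""
        cfg = syn.SimConfig(seed=7, n_chroms=8, n_genes=2000, n_peaks=4000)
        genes = syn.simulate_annotation(cfg)
        peaks, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        lab = syn.simulate_deg_link(cfg, genes, peaks, truth)
        p = lab["p_down"].to_numpy()
        rate = (lab["deg_status"] == "down").mean()
        se = np.sqrt(np.sum(p * (1 - p))) / len(p)
        assert abs(rate - p.mean()) < 3 * se


class TestTTseq:
    def test_deterministic(self):
        cfg = syn.SimConfig(seed=8, n_chroms=1, chrom_length=400_000, n_genes=5,
                            timepoints=(0.0, 1.0))
        genes = syn.simulate_annotation(cfg)
        f1 = syn.simulate_ttseq_coverage(cfg, genes)
        f2 = syn.simulate_ttseq_coverage(cfg, genes)
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_background_rate(self):
        cfg = syn.SimConfig(seed=9, n_chroms=1, chrom_length=400_000, n_genes=5,
                            timepoints=(0.0, 1.0), tu_rate_low=0.0)
        genes = syn.simulate_annotation(cfg)
        frags = syn.simulate_ttseq_coverage(cfg, genes)
        assert (frags["source_gene"] != "").all()

    def test_per_bin_mean_rate(self):
        """Moment check: genic fragment count per bin approximates the high
        rate (interior bins of long genes; boundary bins are clipped)."""
        cfg = syn.SimConfig(seed=10, n_chroms=1, chrom_length=2_000_000,
                            n_genes=40, timepoints=(0.0,), n_replicates=1,
                            tu_rate_low=0.0)
        genes = syn.simulate_annotation(cfg)
        frags = syn.simulate_ttseq_coverage(cfg, genes)
        n_interior = sum(max(0, len(g) // cfg.tu_bin_size - 2) for g in genes)
        interior = 0
        for g in genes:
            sel = frags[(frags.source_gene == g.name)]
            mids = (sel.start + sel.end - 1) // 2
            interior += ((mids >= g.start + cfg.tu_bin_size) &
                         (mids < g.start + (len(g) // cfg.tu_bin_size - 1) * cfg.tu_bin_size)).sum()
        rate = interior / n_interior
        assert abs(rate / cfg.tu_rate_high - 1) < 0.05


class TestSequences:
    @staticmethod
    def _pwm():
        return np.array([
            [0.9, 0.05, 0.05, 0.9, 0.05, 0.9],
            [0.04, 0.05, 0.85, 0.04, 0.05, 0.04],
            [0.03, 0.05, 0.05, 0.03, 0.85, 0.03],
            [0.03, 0.85, 0.05, 0.03, 0.05, 0.03],
        ])

    def test_deterministic(self, sim_bundle):
        cfg, peaks, truth = (
            sim_bundle["cfg"], sim_bundle["peaks"], sim_bundle["truth"],
        )
        s1 = syn.simulate_sequences(cfg, peaks, truth, self._pwm())
        s2 = syn.simulate_sequences(cfg, peaks, truth, self._pwm())
        assert s1 == s2

    def test_gc_zero_gives_at_only_background(self):
        cfg = syn.SimConfig(seed=12, n_peaks=20, motif_base_rate=0.0, motif_odds=1.0)
        genes = syn.simulate_annotation(cfg)
        peaks, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        # monkeypatch-free: GC is drawn per peak; instead verify composition
        # tracks the recorded GC covariate
        seqs = syn.simulate_sequences(cfg, peaks, truth, self._pwm())
        for (name, s), (_, row) in zip(seqs, truth.sequences.iterrows()):
            gc_obs = (s.count("G") + s.count("C")) / len(s)
            assert abs(gc_obs - row["gc"]) < 0.2

    def test_odds_one_equalizes_planting(self):
        """Two-proportion check at n=2000: with odds 1 the planting rate is
        category-independent within binomial error."""
        cfg = syn.SimConfig(seed=13, motif_odds=1.0)
        genes = syn.simulate_annotation(cfg)
        peaks, _, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
        syn.simulate_sequences(cfg, peaks, truth, self._pwm())
        t = truth.sequences.join(truth.peaks["category"])
        p_down = t.loc[t.category == "down_dar", "planted"].mean()
        p_ndar = t.loc[t.category == "ndar", "planted"].mean()
        n1 = (t.category == "down_dar").sum()
        n2 = (t.category == "ndar").sum()
        pbar = cfg.motif_base_rate
        se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        assert abs(p_down - p_ndar) < 3 * se
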