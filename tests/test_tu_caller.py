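import re
from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp

from pioneerdyn import tu_caller as tc
from pioneerdyn.io_core import CoverageTrack, GenomicInterval


def _simulate_chain(params, T, rng):
    states = np.zeros(T, dtype=int)
    states[0] = rng.choice(2, p=params.initial)
    for t in range(1, T):
        states[t] = rng.choice(2, p=params.transition[states[t - 1]])
    rates = np.exp(params.mu[states] + params.sigma[states] * rng.normal(size=T))
    return states, rng.poisson(rates)


@pytest.fixture(scope="module")
def true_params():
    return tc.HMMParams(
        initial=[0.5, 0.5],
        transition=[[0.97, 0.03], [0.05, 0.95]],
        mu=[-2.0, 2.0],
        sigma=[0.4, 0.5],
    )


class TestHMM:
    def test_forward_equals_exhaustive_enumeration(self, true_params, rng):
        counts = rng.poisson([0, 1, 5, 8, 0, 0, 6, 1])
        log_b = tc._emission_matrix(counts, true_params, 20)
        paths = []
        for path in product([0, 1], repeat=8):
            lp = np.log(true_params.initial[path[0]]) + log_b[0, path[0]]
            for t in range(1, 8):
                lp += np.log(true_params.transition[path[t - 1], path[t]]) + log_b[t, path[t]]
            paths.append(lp)
        assert abs(tc.forward_loglik(counts, true_params) - logsumexp(paths)) < 1e-9

    def test_em_monotone_from_truth(self, true_params, rng):
        _, x = _simulate_chain(true_params, 2000, rng)
        _, lls = tc.fit_hmm(x, init=true_params)
        assert np.all(np.diff(lls) >= -1e-8)

    def test_decoding_recovers_states(self, true_params, rng):
        states, x = _simulate_chain(true_params, 5000, rng)
        params, lls = tc.fit_hmm(x)
        assert np.all(np.diff(lls) >= -1e-8)
        dec = tc.decode_states(params, x)
        assert (dec == states).mean() >= 0.95

    def test_posterior_close_to_viterbi_when_separated(self, true_params, rng):
        _, x = _simulate_chain(true_params, 3000, rng)
        params, _ = tc.fit_hmm(x)
        post = tc.decode_states(params, x)
        vit = tc.decode_states(params, x, method="viterbi")
        assert (post == vit).mean() >= 0.99

    def test_tie_goes_to_low_state(self):
        params = tc.HMMParams(
            initial=[0.5, 0.5],
            transition=[[0.5, 0.5], [0.5, 0.5]],
            mu=[1.0, 1.0],
            sigma=[0.5, 0.5],
        )
        labels = tc.decode_states(params, np.array([3, 1, 4]))
        assert (labels == 0).all()

    def test_single_bin_chain(self, true_params):
        lab = tc.decode_states(true_params, np.array([50]))
        log_b = tc._emission_matrix(np.array([50]), true_params, 20)
        expected = int(np.argmax(np.log(true_params.initial) + log_b[0]))
        assert lab[0] == expected

    def test_all_zero_input_degenerates(self):
        with pytest.warns(UserWarning, match="all-zero"):
            params, _ = tc.fit_hmm(np.zeros(50, dtype=int))
        assert params.mu[0] <= params.mu[1]


class TestRunMerging:
    def test_single_interruption_absorbed(self):
        tus = tc.states_to_putative_tus(np.array([1, 1, 0, 1, 1]), "chr1", "+")
        assert len(tus) == 1
        assert (tus[0].interval.start, tus[0].interval.end) == (0, 1000)

    def test_double_gap_preserved(self):
        tus = tc.states_to_putative_tus(np.array([1, 0, 0, 1]), "chr1", "+")
        assert len(tus) == 2

    def test_matches_string_rewriting_oracle(self, rng):
        """HLH -> HHH rewriting then splitting on L runs, on random labels."""
        for _ in range(300):
            labels = rng.integers(0, 2, size=rng.integers(1, 40))
            s = "".join("H" if x else "L" for x in labels)
            rewritten = re.sub("(?<=H)L(?=H)", "H", s)
            expected = [(m.start(), m.end()) for m in re.finditer("H+", rewritten)]
            tus = tc.states_to_putative_tus(labels, "chr1", "+")
            got = [
                (tu.interval.start // 200, tu.interval.end // 200) for tu in tus
            ]
            assert got == expected


class TestFragmentFilters:
    def _tu(self, start, end):
        return tc.TranscribedUnit(interval=GenomicInterval("chr1", start, end, "+"))

    def test_putative_filter_is_strict(self):
        frags25 = [GenomicInterval("chr1", 10 + i, 60 + i, "+") for i in range(25)]
        assert tc.filter_putative_tus([self._tu(0, 1000)], frags25) == []
        frags26 = frags25 + [GenomicInterval("chr1", 40, 90, "+")]
        assert len(tc.filter_putative_tus([self._tu(0, 1000)], frags26)) == 1

    def test_counts_match_naive_loop(self, rng):
        frags = []
        for _ in range(2000):
            s = int(rng.integers(0, 100_000))
            frags.append(GenomicInterval("chr1", s, s + 150, "+"))
        tus = []
        for _ in range(200):
            s = int(rng.integers(0, 95_000))
            tus.append(self._tu(s, s + int(rng.integers(200, 5000))))
        kept = tc.filter_putative_tus(tus, frags)
        expected = [
            tu for tu in tus
            if sum(f.start < tu.interval.end and f.end > tu.interval.start for f in frags) > 25
        ]
        assert [t.interval for t in kept] == [t.interval for t in expected]

    def test_count_filter_boundaries(self):
        tu = self._tu(0, 1000)
        mk = lambda n: [GenomicInterval("chr1", 10, 200, "+")] * n
        # (10, 10, 30): only one sample strictly exceeds 10 -> dropped
        kept, _ = tc.count_and_filter_tus(
            [tu], {"s1": mk(10), "s2": mk(10), "s3": mk(30)}
        )
        assert kept == []
        # (11, 11, 0): two samples exceed -> kept
        kept, counts = tc.count_and_filter_tus(
            [tu], {"s1": mk(11), "s2": mk(11), "s3": []}
        )
        assert len(kept) == 1
        assert counts.iloc[0].tolist() == [11, 11, 0]


class TestRefinement:
    def test_step_coverage_moves_start(self):
        vals = np.zeros(3000)
        vals[1050:] = 3.0  # step of +3 between 1049 and 1050
        cov = CoverageTrack("chr1", vals)
        tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 1000, 2000, "+"))
        ref = tc.refine_boundaries(tu, cov)
        assert ref.interval.start == 1050

    def test_flat_coverage_unchanged(self):
        cov = CoverageTrack("chr1", np.full(3000, 2.0))
        tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 1000, 2000, "+"))
        ref = tc.refine_boundaries(tu, cov)
        assert (ref.interval.start, ref.interval.end) == (1000, 2000)

    def test_refined_boundary_within_half_window(self, rng):
        for _ in range(50):
            vals = rng.integers(0, 6, size=4000).astype(float)
            cov = CoverageTrack("chr1", vals)
            tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 1400, 2600, "+"))
            ref = tc.refine_boundaries(tu, cov)
            assert abs(ref.interval.start - 1400) <= 200
            assert abs(ref.interval.end - 2600) <= 200


class TestGeneAssociation:
    def test_identical_gene_jaccard_one(self):
        g = GenomicInterval("chr1", 1000, 5000, "+", "gA")
        tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 1000, 5000, "+"))
        (out,) = tc.associate_tus_genes([tu], [g])
        assert out.gene_ids == ["gA"] and not out.multi_small_flag

    def test_many_small_genes_flagged(self):
        genes = [
            GenomicInterval("chr1", s, s + 500, "+", f"mi{i}")
            for i, s in enumerate((10_000, 40_000, 80_000))
        ]
        tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 0, 100_000, "+"))
        (out,) = tc.associate_tus_genes([tu], genes)
        # per-gene Jaccard = 500 / 100000 = 0.005 < 0.02
        assert out.multi_small_flag and len(out.gene_ids) == 3

    def test_no_overlap_empty(self):
        g = GenomicInterval("chr1", 50_000, 60_000, "-", "g1")
        tu = tc.TranscribedUnit(interval=GenomicInterval("chr1", 0, 1000, "+"))
        (out,) = tc.associate_tus_genes([tu], [g])
        assert out.gene_ids == []


class TestSplitting:
    def _setup(self, step):
        genes = [
            GenomicInterval("chr1", 10_000, 30_000, "+", "gA"),
            GenomicInterval("chr1", 50_000, 70_000, "+", "gB"),
        ]
        vals = np.zeros(100_000)
        vals[10_000:50_000] = 2.0
        vals[50_000:70_000] = 2.0 + step  # wave at gB's TSS
        tu = tc.TranscribedUnit(
            interval=GenomicInterval("chr1", 10_000, 70_000, "+", "tu1"),
            gene_ids=["gA", "gB"],
        )
        return genes, CoverageTrack("chr1", vals), tu

    def test_split_at_internal_tss_with_wave(self):
        genes, cov, tu = self._setup(step=6.0)
        parts = tc.split_tus_at_internal_tss(tu, genes, cov)
        assert len(parts) == 2
        assert parts[0].interval.end == 50_000 == parts[1].interval.start
        # children partition the parent
        assert parts[0].interval.start == 10_000 and parts[1].interval.end == 70_000

    def test_subthreshold_wave_no_split(self):
        genes, cov, tu = self._setup(step=4.0)
        assert len(tc.split_tus_at_internal_tss(tu, genes, cov)) == 1

    def test_single_gene_unchanged(self):
        genes, cov, tu = self._setup(step=6.0)
        tu.gene_ids = ["gA"]
        assert tc.split_tus_at_internal_tss(tu, genes, cov) == [tu]


class TestEndToEnd:
    def test_strand_separation(self):
        """Plus- and minus-strand calls never share fragments."""
        import pandas as pd
        from pioneerdyn import synthetic as syn

        cfg = syn.SimConfig(
            seed=21, n_chroms=1, chrom_length=400_000, n_genes=6,
            timepoints=(0.0, 1.0), tu_rate_low=0.0,
        )
        genes = syn.simulate_annotation(cfg)
        frags = syn.simulate_ttseq_coverage(cfg, genes)
        tus, _ = tc.call_tus(frags, genes, cfg.chrom_length)
        for tu in tus:
            strands = {
                g.strand for g in genes if g.name in tu.gene_ids
            }
            assert strands <= {tu.interval.strand}
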