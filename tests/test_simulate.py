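import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wdge import (
    NoiseSpec,
    SimTruth,
    SynthConfig,
    apply_noise,
    apply_upregulation,
    generate_synthetic,
    noise_amplitude,
    noise_fn,
    plant_effects,
    subsample_umis,
    tally_benchmark,
)
from wdge.simulate import rng_for


class TestSubsample:
    def test_retain_one_identity(self, small_synth):
        out = subsample_umis(small_synth, 1.0, seed=0)
        assert (out.counts != small_synth.counts).nnz == 0

    def test_retain_zero_empties(self, small_synth):
        out = subsample_umis(small_synth, 0.0, seed=0)
        assert out.counts.nnz == 0

    def test_binomial_never_increases_and_preserves_zeros(self, small_synth):
        out = subsample_umis(small_synth, 0.4, seed=3)
        diff = (small_synth.counts - out.counts).toarray()
        assert (diff >= 0).all()
        orig_zero = small_synth.counts.toarray() == 0
        assert (out.counts.toarray()[orig_zero] == 0).all()

    def test_binomial_retained_fraction(self, base_cm):
        total = base_cm.counts.sum()
        out = subsample_umis(base_cm, 0.4, seed=5)
        frac = out.counts.sum() / total
        assert frac == pytest.approx(0.4, abs=0.002)

    def test_per_gene_exact_totals(self, small_synth):
        out = subsample_umis(small_synth, 0.4, seed=7, mode="per_gene_exact")
        got = np.asarray(out.counts.sum(axis=1)).ravel()
        want = np.round(0.4 * np.asarray(small_synth.counts.sum(axis=1)).ravel())
        assert np.array_equal(got, want)

    def test_seed_reproducible(self, small_synth):
        a = subsample_umis(small_synth, 0.4, seed=11)
        b = subsample_umis(small_synth, 0.4, seed=11)
        assert (a.counts != b.counts).nnz == 0


class TestNoiseFn:
    def test_zero_count_always_zero(self):
        rng = rng_for(0, "t")
        assert (noise_fn(5.0, np.zeros(1000, dtype=int), rng) == 0).all()

    def test_zero_mean(self):
        rng = rng_for(1, "t")
        draws = noise_fn(5.0, np.full(100_000, 100), rng)
        amp = noise_amplitude(5.0, 100)
        assert abs(draws.mean()) < 3 * amp / np.sqrt(3 * 100_000)

    def test_asymptotic_variance_law(self):
        rng = rng_for(2, "t")
        N = 10_000
        draws = noise_fn(5.0, np.full(100_000, N), rng)
        assert draws.var() / N == pytest.approx(5.0, abs=0.15)

    def test_amplitude_bound_and_symmetry(self):
        rng = rng_for(3, "t")
        N = 50
        draws = noise_fn(5.0, np.full(100_000, N), rng)
        assert np.abs(draws).max() <= np.ceil(noise_amplitude(5.0, N))
        ks = stats.ks_2samp(draws, -draws)
        assert ks.pvalue > 0.01

    def test_alpha_range_enforced(self):
        with pytest.raises(ValueError):
            noise_fn(12.0, np.array([5]), rng_for(0, "t"))

    def test_variance_ratio_converges(self):
        rng = rng_for(4, "t")
        for N in (10_000, 100_000):
            draws = noise_fn(3.0, np.full(100_000, N), rng)
            assert draws.var() / (3.0 * N) == pytest.approx(1.0, abs=0.03)


class TestApplyNoise:
    def test_empty_target_identity(self, small_synth):
        out = apply_noise(small_synth, NoiseSpec(5.0, [], seed=0))
        assert (out.counts != small_synth.counts).nnz == 0

    def test_nonnegative(self, small_synth):
        genes = list(small_synth.gene_ids[:100])
        out = apply_noise(small_synth, NoiseSpec(5.0, genes, seed=1))
        assert out.counts.data.min() >= 0

    def test_gene_totals_approximately_preserved(self, base_cm):
        """Zero-mean noise: per-gene totals move by at most a few noise SDs
        (Var of the total change is alpha * total) and show no net bias."""
        totals = np.asarray(base_cm.counts.sum(axis=1)).ravel()
        big = np.flatnonzero(totals >= 10_000)[:50]
        genes = list(base_cm.gene_ids[big])
        alpha = 5.0
        out = apply_noise(base_cm, NoiseSpec(alpha, genes, seed=2))
        new_totals = np.asarray(out.counts.sum(axis=1)).ravel()[big]
        dev = (new_totals - totals[big]) / totals[big]
        assert (np.abs(dev) < 4.0 * np.sqrt(alpha / totals[big])).all()
        assert abs(dev.mean()) < 0.005


class TestUpregulation:
    def test_beta_one_identity(self, small_synth):
        out = apply_upregulation(small_synth, list(small_synth.gene_ids[:5]), 1.0)
        assert (out.counts != small_synth.counts).nnz == 0

    def test_even_counts_exact_fifty_percent(self):
        import scipy.sparse as sp
        from wdge import CountMatrix

        cm = CountMatrix(
            sp.csr_matrix(np.array([[2, 4, 10]])), ["g"], ["a", "b", "c"]
        )
        out = apply_upregulation(cm, ["g"], 1.5)
        assert out.counts.toarray().tolist() == [[3, 6, 15]]

    def test_beta_1_3_realized_increase_with_rounding_loss(self, base_cm):
        """Enumeration over integer counts: round-half-even of 0.3·N loses
        part of the nominal 30% for moderate-expression genes."""
        per_cell = np.asarray(base_cm.counts.sum(axis=1)).ravel() / base_cm.n_cells
        moderate = np.flatnonzero((per_cell >= 0.3) & (per_cell <= 3.0))
        values = base_cm.counts[moderate].tocoo().data
        freq = np.bincount(values, minlength=21)[:21]
        ns = np.arange(21)
        realized = (freq * np.round(0.3 * ns)).sum() / (freq * ns).sum()
        assert 0.25 <= realized <= 0.30
        # and the operation itself matches that enumeration on those rows
        genes = list(base_cm.gene_ids[moderate[:50]])
        out = apply_upregulation(base_cm, genes, 1.3)
        before = np.asarray(base_cm.counts[moderate[:50]].sum(axis=1)).ravel()
        after = np.asarray(out.counts[moderate[:50]].sum(axis=1)).ravel()
        agg_inc = (after.sum() - before.sum()) / before.sum()
        assert 0.25 <= agg_inc <= 0.30


class TestGenerator:
    def test_column_sums_equal_depths(self, small_synth):
        # multinomial per cell: totals are exactly the drawn depths
        assert (small_synth.cell_totals > 0).all()
        dense_sum = np.asarray(small_synth.counts.sum(axis=0)).ravel()
        assert np.array_equal(dense_sum, small_synth.cell_totals)

    def test_seed_bit_identical(self):
        cfg = SynthConfig(n_cells=40, n_genes=100, seed=9)
        a, _ = generate_synthetic(cfg)
        b, _ = generate_synthetic(cfg)
        assert (a.counts != b.counts).nnz == 0

    def test_zero_dispersion_gives_zero_icc(self):
        from wdge import CellGroup, gene_profiles

        cfg = SynthConfig(
            n_cells=300, n_genes=150, dispersion_log10_range=(-8.0, -8.0), seed=13
        )
        cm, _ = generate_synthetic(cfg)
        prof = gene_profiles(cm.counts, cm.cell_totals)
        totals = np.asarray(cm.counts.sum(axis=1)).ravel()
        assert np.median(prof["rho"][totals > 100]) < 0.01

    def test_dispersion_spread_produces_wdc_spread(self, base_cm):
        """Three decades of planted dispersion yield WDC values spanning from
        near 0 (biological variance dominates) to ~1 (counting noise)."""
        from wdge import gene_profiles, filter_genes_min_total

        genes = filter_genes_min_total(base_cm, None, 1000)
        prof = gene_profiles(base_cm.counts[genes], base_cm.cell_totals)
        w = prof["wdc"]
        assert np.nanmin(w) < 0.2
        assert np.nanmax(w) > 0.8

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_cells=0)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**20))
    def test_depth_multiplier_scales_depths(self, seed):
        base = SynthConfig(n_cells=20, n_genes=50, seed=seed)
        double = SynthConfig(n_cells=20, n_genes=50, seed=seed, group_depth_multiplier=2.0)
        a, _ = generate_synthetic(base)
        b, _ = generate_synthetic(double)
        ratio = b.cell_totals / a.cell_totals
        assert np.all(ratio > 1.8)


class TestPlantAndTally:
    def test_plant_effects_statuses(self, small_synth):
        noise = list(small_synth.gene_ids[:20])
        up = noise[:5]
        _, truth = plant_effects(small_synth, noise, up, seed=0)
        assert (truth.status == "upregulated").sum() == 5
        assert (truth.status == "noise_only").sum() == 15
        assert truth.beta[up[0]] == 1.5

    def test_all_null_all_p_one_gives_zero_fp(self):
        genes = [f"g{i}" for i in range(10)]
        truth = SimTruth(pd.Series("unmodified", index=genes))
        tab = pd.DataFrame({"gene": genes, "p_combined": 1.0, "log2fc_w": 0.0})
        rep = tally_benchmark([tab], truth, thresholds=(0.05,), tests=("p_combined",))
        assert (rep["fp_median"] == 0.0).all()

    def test_all_planted_detected_gives_zero_fn(self):
        genes = [f"g{i}" for i in range(10)]
        truth = SimTruth(pd.Series("upregulated", index=genes))
        tab = pd.DataFrame({"gene": genes, "p_combined": 0.0, "log2fc_w": 1.0})
        rep = tally_benchmark([tab], truth, thresholds=(0.05,), tests=("p_combined",))
        assert (rep["fn_median"] == 0.0).all()

    def test_hand_tallied_fixture(self):
        genes = [f"g{i}" for i in range(10)]
        status = pd.Series(
            ["upregulated"] * 4 + ["noise_only"] * 6, index=genes
        )
        truth = SimTruth(status)
        p = [0.001, 0.2, 0.001, 0.001, 0.001, 0.5, 0.5, 0.5, 0.5, 0.5]
        fc = [1.0, 1.0, 0.05, 1.0, 1.0, 0, 0, 0, 0, 0]
        tab = pd.DataFrame({"gene": genes, "p_combined": p, "log2fc_w": fc})
        rep = tally_benchmark([tab], truth, thresholds=(0.05,), tests=("p_combined",))
        rep = rep.set_index("mode")
        # p-only: detected g0,g2,g3 of planted (FN 1/4); g4 of null (FP 1/6)
        assert rep.loc["p", "fn_median"] == pytest.approx(0.25)
        assert rep.loc["p", "fp_median"] == pytest.approx(1 / 6)
        # p+fc: g2 fails the fold-change threshold too (FN 2/4)
        assert rep.loc["p_fc", "fn_median"] == pytest.approx(0.5)
        assert rep.loc["p_fc", "fp_median"] == pytest.approx(1 / 6)

    def test_gene_mismatch_rejected(self):
        truth = SimTruth(pd.Series("unmodified", index=["g0"]))
        tab = pd.DataFrame({"gene": ["other"], "p_combined": [0.5], "log2fc_w": [0.0]})
        with pytest.raises(ValueError):
            tally_benchmark([tab], truth, tests=("p_combined",))


class TestRngStreams:
    def test_stable_across_calls(self):
        a = rng_for(42, "x").integers(0, 2**31, 5)
        b = rng_for(42, "x").integers(0, 2**31, 5)
        c = rng_for(42, "y").integers(0, 2**31, 5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
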