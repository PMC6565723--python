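"""Capture, amplification, fragmentation, sequencing and batch effects."""

import numpy as np
import pytest
from scipy import stats

from telesim import TechParams, true2observed
from telesim.libprep import (
    FragmentPool,
    MoleculePool,
    add_batch_effects,
    amplification_rates,
    amplify_fragments,
    capture,
    fragment,
    fragment_counts_per_copy,
    preamplify,
    sequence_and_count,
)


def make_pool(copies, genes=None, cells=None, lengths=None,
              n_genes=None, n_cells=1):
    copies = np.asarray(copies, dtype=np.int64)
    genes = np.zeros(copies.size, int) if genes is None else np.asarray(genes)
    cells = np.zeros(copies.size, int) if cells is None else np.asarray(cells)
    n_genes = int(genes.max()) + 1 if n_genes is None else n_genes
    lengths = np.full(n_genes, 1000) if lengths is None else np.asarray(lengths)
    return MoleculePool(gene=genes, cell=cells, copies=copies,
                        gene_lengths=lengths, n_genes=n_genes,
                        n_cells=n_cells)


class TestCapture:
    def test_full_capture_retains_everything(self, rng):
        true = rng.poisson(5.0, size=(20, 10))
        pool, alpha = capture(true, np.full(20, 1000), 1.0, 0.0, rng)
        assert np.allclose(alpha, 1.0)
        assert np.array_equal(pool.counts_matrix(), true)

    def test_binomial_thinning_gof(self, rng):
        # one gene with true count 10 in many cells, alpha = 0.2 exactly:
        # retained ~ Binomial(10, 0.2); chi-square GOF against the exact pmf
        n_cells = 100_000
        true = np.full((1, n_cells), 10)
        pool, _ = capture(true, np.array([500]), 0.2, 0.0, rng)
        retained = pool.counts_matrix()[0]
        observed = np.bincount(retained, minlength=11)
        expected = stats.binom(10, 0.2).pmf(np.arange(11)) * n_cells
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2(keep.sum() - 1).sf(chi2) > 0.01

    def test_alpha_shared_within_cell(self, rng):
        # realised efficiency is one number per cell: with huge counts the
        # per-gene retention fractions within a cell concentrate on alpha_hat
        true = np.full((50, 4), 20_000)
        pool, alpha = capture(true, np.full(50, 500), 0.5, 0.2, rng)
        counts = pool.counts_matrix()
        fracs = counts / true
        assert np.allclose(fracs, alpha[None, :], atol=0.02)
        assert alpha.std() > 0.01  # cells differ

    def test_invalid_alpha(self, rng):
        with pytest.raises(ValueError):
            capture(np.ones((2, 2), int), np.ones(2), 0.0, 0.1, rng)


class ZeroNormalRng:
    """rng stub whose normal() is exactly zero (isolates systematic bias)."""

    def normal(self, loc, scale, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestAmplificationRates:
    def test_no_bias_gives_basal_rate(self, rng):
        rates = amplification_rates(np.arange(100, 2100, 20), 0.7,
                                    lenslope=0.0, MaxAmpBias=0.0, rng=rng)
        assert np.allclose(rates, 0.7)

    def test_length_bias_magnitudes_match_hand_calculation(self):
        # nbins=20, lenslope=0.023: bin ranks 1..20, median 10.5, so the
        # extreme systematic biases are +/- 0.023*9.5 = 0.2185 and the
        # residual random-bias scale is 0.3 - 0.2185 = 0.0815
        lengths = np.arange(200, 200 + 2000 * 20, 20)
        rates = amplification_rates(lengths, 0.7, lenslope=0.023,
                                    MaxAmpBias=0.3, nbins=20,
                                    rng=ZeroNormalRng())
        assert rates.max() == pytest.approx(0.7 + 0.2185)
        assert rates.min() == pytest.approx(0.7 - 0.2185)
        # longest genes amplify worst
        assert rates[np.argsort(lengths)][-1] < rates[np.argsort(lengths)][0]
        assert 0.3 - 0.2185 == pytest.approx(0.0815)

    def test_boundary_lenslope_rejected(self, rng):
        with pytest.raises(ValueError):
            amplification_rates(np.arange(100, 2100, 100), 0.7,
                                lenslope=2 * 0.3 / 19, MaxAmpBias=0.3,
                                nbins=20, rng=rng)


class TestPreamplify:
    def test_rate_one_doubles_each_cycle(self, rng):
        pool = make_pool([1, 3, 7])
        out = preamplify(pool, np.array([1.0]), 1, rng)
        assert np.array_equal(out.copies, [2, 6, 14])

    def test_rate_zero_is_identity(self, rng):
        pool = make_pool([1, 3, 7])
        out = preamplify(pool, np.array([0.0]), 5, rng)
        assert np.array_equal(out.copies, [1, 3, 7])

    def test_branching_expectation(self, rng):
        # E[copies after N cycles] = (1+r)^N per initial copy
        n_mol, r, n_cycles = 10_000, 0.6, 4
        pool = make_pool(np.ones(n_mol, dtype=np.int64))
        out = preamplify(pool, np.array([r]), n_cycles, rng)
        expected = (1 + r) ** n_cycles
        se = out.copies.std() / np.sqrt(n_mol)
        assert abs(out.copies.mean() - expected) < 3 * se

    def test_linear_amplification_no_compounding(self, rng):
        pool = make_pool([2, 5])
        out = preamplify(pool, np.array([0.7]), 10, rng,
                         linear_amp=True, linear_amp_rounds=12)
        assert np.array_equal(out.copies, [2 * round(0.7 * 12), 5 * round(0.7 * 12)])


class TestFragment:
    def test_umi_keeps_at_most_one_fragment_per_copy(self, rng):
        pool = make_pool(np.full(200, 3), lengths=np.array([3000]))
        out = fragment(pool, "UMI", rng=rng)
        assert np.all(out.fragments <= pool.copies)

    def test_short_transcript_filtered_out(self, rng):
        # an 80 bp transcript can never yield a fragment in [100, 1000]
        pool = make_pool(np.ones(100, dtype=np.int64), lengths=np.array([80]))
        for protocol in ("UMI", "nonUMI"):
            out = fragment(pool, protocol, rng=rng)
            assert not out.fragments.any()

    def test_mean_fragment_length_calibrated(self, gene_length_table, rng):
        lengths = rng.choice(gene_length_table, size=10_000)
        n_frags = fragment_counts_per_copy(lengths, 400.0, rng)
        mean_len = lengths.sum() / n_frags.sum()
        assert abs(mean_len - 400.0) / 400.0 < 0.05


class TestAmplifyFragments:
    def test_identity_and_doubling(self, rng):
        pool = make_pool([1, 1, 1])
        frags = FragmentPool(pool, np.array([2, 4, 8], dtype=np.int64))
        same = amplify_fragments(frags, np.array([0.0]), 3, rng)
        assert np.array_equal(same.fragments, [2, 4, 8])
        double = amplify_fragments(frags, np.array([1.0]), 1, rng)
        assert np.array_equal(double.fragments, [4, 8, 16])

    def test_branching_expectation(self, rng):
        pool = make_pool(np.ones(5000, dtype=np.int64))
        frags = FragmentPool(pool, np.ones(5000, dtype=np.int64))
        out = amplify_fragments(frags, np.array([0.3]), 6, rng)
        expected = 1.3 ** 6
        se = out.fragments.std() / np.sqrt(5000)
        assert abs(out.fragments.mean() - expected) < 3 * se


class TestSequenceAndCount:
    def test_saturating_depth_reads_everything(self, rng):
        pool = make_pool([1, 1, 1], genes=[0, 1, 1], n_genes=2)
        frags = FragmentPool(pool, np.array([5, 3, 2], dtype=np.int64))
        out = sequence_and_count(frags, 1e6, 0.0, "nonUMI", rng)
        assert np.array_equal(out.counts[:, 0], [5, 5])
        umi = sequence_and_count(frags, 1e6, 0.0, "UMI", rng)
        assert np.array_equal(umi.counts[:, 0], [1, 2])

    def test_zero_depth_gives_zero_matrix(self, rng):
        pool = make_pool([1, 1], genes=[0, 1], n_genes=2)
        frags = FragmentPool(pool, np.array([5, 5], dtype=np.int64))
        out = sequence_and_count(frags, 1e-9, 0.0, "nonUMI", rng)
        assert not out.counts.any()

    def test_reads_follow_hypergeometric_law(self, rng):
        # 3-gene toy pool (one fragment bucket per gene), fixed depth:
        # per-gene reads ~ multivariate hypergeometric; chi-square GOF of
        # gene 0's marginal against the exact univariate hypergeometric
        colors = np.array([6, 4, 2], dtype=np.int64)
        depth = 5
        reps = 20_000
        obs = np.zeros(min(depth, colors[0]) + 1)
        for _ in range(reps):
            pool = make_pool([1, 1, 1], genes=[0, 1, 2], n_genes=3)
            frags = FragmentPool(pool, colors.copy())
            out = sequence_and_count(frags, depth, 0.0, "nonUMI", rng)
            obs[out.counts[0, 0]] += 1
        support = np.arange(obs.size)
        expected = stats.hypergeom(colors.sum(), colors[0], depth).pmf(support) * reps
        keep = expected > 5
        chi2 = ((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2(keep.sum() - 1).sf(chi2) > 0.01


class TestBatchEffects:
    def _obs(self, rng, n_genes=30, n_cells=40):
        from telesim.libprep import ObservedCountsResult
        return ObservedCountsResult(
            counts=rng.poisson(20.0, size=(n_genes, n_cells)),
            protocol="UMI", capture_eff=np.full(n_cells, 0.1),
            depths=np.full(n_cells, 1000), amp_rates=np.full(n_genes, 0.7))

    def test_single_batch_is_identity(self, rng):
        obs = self._obs(rng)
        out = add_batch_effects(obs, 1, 0.5, rng)
        assert np.array_equal(out.counts, obs.counts)
        assert set(out.batch) == {0}

    def test_zero_sd_is_identity(self, rng):
        obs = self._obs(rng)
        out = add_batch_effects(obs, 3, 0.0, rng)
        assert np.array_equal(out.counts, obs.counts)

    def test_log_ratio_recovers_factor_difference(self):
        # large counts, two batches: per-gene mean log2 ratio between the
        # batches estimates the simulated log2-factor difference
        rng = np.random.default_rng(77)
        from telesim.libprep import ObservedCountsResult
        n_genes, n_cells = 200, 1000
        obs = ObservedCountsResult(
            counts=np.full((n_genes, n_cells), 1000),
            protocol="UMI", capture_eff=np.full(n_cells, 0.1),
            depths=np.full(n_cells, 1000), amp_rates=np.full(n_genes, 0.7))
        out = add_batch_effects(obs, 2, 0.5, rng)
        in_b0 = out.batch == 0
        ratio = np.log2(out.counts[:, in_b0].mean(axis=1)
                        / out.counts[:, ~in_b0].mean(axis=1))
        # the applied log2 factors are N(0, 0.5) per gene/batch, so the
        # per-gene ratios are N(0, 0.5*sqrt(2)); check scale recovery
        assert ratio.std() == pytest.approx(0.5 * np.sqrt(2), rel=0.15)
        assert abs(ratio.mean()) < 5 * ratio.std() / np.sqrt(n_genes)


class TestFullPipeline:
    def test_umi_counts_never_exceed_true(self, rng):
        true = rng.poisson(8.0, size=(60, 40))
        tech = TechParams(protocol="UMI", alpha_mean=0.3, alpha_sd=0.02,
                          nPCR1=4, nPCR2=2, depth_mean=5e4, depth_sd=0.0)
        lengths = rng.integers(500, 5000, size=60)
        out = true2observed(true, tech, lengths, rng)
        assert np.all(out.counts <= true)

    def test_same_seed_bit_identical(self):
        true = np.random.default_rng(1).poisson(5.0, size=(30, 20))
        tech = TechParams(nPCR1=3, nPCR2=2, depth_mean=2e4)
        lengths = np.random.default_rng(2).integers(500, 5000, size=30)
        a = true2observed(true, tech, lengths, np.random.default_rng(42))
        b = true2observed(true, tech, lengths, np.random.default_rng(42))
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.depths, b.depths)

    def test_good_parameters_track_truth_better_than_bad(self):
        # high capture / low bias preserves the true expression ranking
        # better than low capture / high bias
        rng = np.random.default_rng(31)
        true = rng.poisson(rng.uniform(1, 80, size=(150, 25)))
        lengths = rng.integers(500, 8000, size=150)
        good = TechParams(protocol="nonUMI", alpha_mean=0.2, alpha_sd=0.01,
                          MaxAmpBias=0.1, lenslope=0.01, nPCR1=8, nPCR2=4,
                          depth_mean=1e5, depth_sd=100.0)
        bad = TechParams(protocol="nonUMI", alpha_mean=0.05, alpha_sd=0.01,
                         MaxAmpBias=0.2, lenslope=0.02, nPCR1=8, nPCR2=4,
                         depth_mean=1e5, depth_sd=100.0)
        rho = {}
        for name, tech in (("good", good), ("bad", bad)):
            out = true2observed(true, tech, lengths,
                                np.random.default_rng(99))
            rho[name] = stats.spearmanr(true.ravel(),
                                        out.counts.ravel()).statistic
        assert rho["good"] > rho["bad"]

    def test_umi_less_noisy_than_nonumi(self):
        # per-gene CV of observed counts, identical upstream true counts
        rng = np.random.default_rng(53)
        true = np.tile(rng.poisson(30.0, size=(80, 1)), (1, 40))
        lengths = rng.integers(500, 5000, size=80)
        cvs = {}
        for protocol, depth in (("UMI", 5e4), ("nonUMI", 5e5)):
            tech = TechParams(protocol=protocol, alpha_mean=0.2,
                              alpha_sd=0.0, nPCR1=8, nPCR2=4,
                              depth_mean=depth, depth_sd=0.0)
            out = true2observed(true, tech, lengths,
                                np.random.default_rng(7))
            counts = out.counts.astype(float)
            keep = counts.mean(axis=1) > 0
            cv = counts[keep].std(axis=1) / counts[keep].mean(axis=1)
            cvs[protocol] = cv.mean()
        assert cvs["UMI"] < cvs["nonUMI"]
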