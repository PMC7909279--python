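"""Tests for the MCMC deconvolution engine.

The haplotype-update kernels are checked against brute-force enumeration of
the exact conditional posterior on tiny instances, where every (donor,
haplotype) configuration can be scored directly with scipy's binomial pmf.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import mitophase as mp
from mitophase import engine as eng

from conftest import toy_haplotypes, toy_loci


def _counts(ref, alt):
    return mp.SiteCountTable(toy_loci(len(ref)), ref, alt)


def _result(proportions, trace=None, n_kept=None):
    trace = np.asarray(trace if trace is not None else np.zeros(100), dtype=float)
    k = len(proportions)
    return eng.DeconvolutionResult(
        proportions=np.asarray(proportions, float),
        haplotypes=np.zeros((k, 1), dtype=np.int8),
        allele_posteriors=np.zeros((k, 1)),
        trace=trace,
        proportion_trace=np.tile(proportions, (trace.size, 1)),
        acceptance_rate=0.5,
        geweke_z=0.0,
        converged=True,
        n_kept=n_kept if n_kept is not None else trace.size,
        config=mp.EngineConfig(k=k),
    )


class TestLogLikelihood:
    def test_all_reference_single_strain_closed_form(self):
        counts = _counts([100] * 5, [0] * 5)
        got = mp.log_likelihood([1.0], np.zeros((1, 5)), counts, mp.EngineConfig(k=1))
        expected = 5 * sps.binom.logpmf(0, 100, 0.01)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_error_folded_allele_fraction(self):
        # w=(0.8,0.2), h1=1, h2=0 -> pi = 0.8*0.99 + 0.2*0.01 = 0.794
        counts = _counts([21], [79])
        got = mp.log_likelihood([0.8, 0.2], [[1], [0]], counts)
        assert got == pytest.approx(float(sps.binom.logpmf(79, 100, 0.794)), rel=1e-12)

    def test_zero_error_limit(self):
        cfg = mp.EngineConfig(k=1, read_error=0.0)
        consistent = mp.log_likelihood([1.0], [[1]], _counts([0], [50]), cfg)
        assert consistent == pytest.approx(0.0, abs=1e-12)
        inconsistent = mp.log_likelihood([1.0], [[0]], _counts([0], [50]), cfg)
        assert np.isfinite(inconsistent) and inconsistent <= eng._LOG_FLOOR

    def test_zero_depth_sites_contribute_nothing(self):
        with_gap = mp.log_likelihood([1.0], [[1, 0]], _counts([0, 0], [50, 0]),
                                     mp.EngineConfig(k=1))
        without = mp.log_likelihood([1.0], [[1]], _counts([0], [50]), mp.EngineConfig(k=1))
        assert with_gap == pytest.approx(without)


class TestUpdateProportions:
    def test_zero_scale_proposal_is_identity_and_accepted(self):
        cfg = mp.EngineConfig(proposal_sd=0.0)
        lik = eng._Likelihood(_counts([80], [20]), cfg)
        state = eng.EngineState(np.array([0.3, -0.3]), np.array([[1], [0]], np.int8),
                                np.zeros(2, np.int64))
        new, accepted = eng.update_proportions(state, lik, cfg, np.random.default_rng(0))
        assert accepted
        assert np.allclose(new.titres, state.titres)

    def test_single_strain_proportion_is_always_one(self):
        cfg = mp.EngineConfig(k=1)
        lik = eng._Likelihood(_counts([80], [20]), cfg)
        state = eng.EngineState(np.zeros(1), np.array([[1]], np.int8), np.zeros(1, np.int64))
        rng = np.random.default_rng(0)
        for _ in range(50):
            state, _ = eng.update_proportions(state, lik, cfg, rng)
            assert state.proportions == pytest.approx([1.0])

    def test_acceptance_rate_moderate_on_two_to_one_mixture(self, small_suite):
        truth = next(t for t in small_suite.mixtures if t.spec.ratio == (2, 1))
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        res = mp.run_mcmc(truth.counts, panel, mp.EngineConfig(seed=3, n_steps=1500))
        assert 0.1 < res.acceptance_rate < 0.9


def _enumerate_joint(counts, panel_matrix, w, cfg):
    """Brute-force conditional posterior over (h_1, h_2), donors marginalized."""
    m = panel_matrix.shape[1]
    mu = cfg.miscopy_rate
    probs = {}
    for h1 in itertools.product((0, 1), repeat=m):
        for h2 in itertools.product((0, 1), repeat=m):
            q = w[0] * np.array(h1) + w[1] * np.array(h2)
            pi = q * (1 - cfg.read_error) + (1 - q) * cfg.read_error
            ll = sps.binom.logpmf(counts.alt_counts, counts.depth, pi).sum()
            total = 0.0
            for donors in itertools.product(range(panel_matrix.shape[0]), repeat=2):
                em = 1.0
                for hap, z in zip((h1, h2), donors):
                    matches = (np.array(hap) == panel_matrix[z]).sum()
                    em *= (1 - mu) ** matches * mu ** (m - matches)
                total += em
            probs[(h1, h2)] = np.exp(ll) * total
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}


class TestGibbsKernelsAgainstEnumeration:
    """Sampled kernel frequencies must match exhaustive enumeration."""

    counts = None

    def setup_method(self):
        self.cfg = mp.EngineConfig(seed=0)
        self.panel_matrix = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        major, minor = np.array([1, 0, 1]), np.array([0, 1, 0])
        q = 0.8 * major + 0.2 * minor
        alt = np.round(100 * q).astype(int)
        self.counts = _counts((100 - alt).tolist(), alt.tolist())
        self.w = np.array([0.8, 0.2])

    def test_single_strain_block_draw_matches_conditional(self):
        """update_haplotype draws (z_k, h_k) from its exact conditional."""
        cfg, mat = self.cfg, self.panel_matrix
        lik = eng._Likelihood(self.counts, cfg)
        other = np.array([1, 0, 1], dtype=np.int8)  # fixed strain 0 = major
        mu = cfg.miscopy_rate

        # oracle: p(z, h) for strain 1 given strain 0, proportions w
        weights = {}
        for z in range(mat.shape[0]):
            for h in itertools.product((0, 1), repeat=3):
                q = self.w[0] * other + self.w[1] * np.array(h)
                pi = q * (1 - cfg.read_error) + (1 - q) * cfg.read_error
                ll = sps.binom.logpmf(self.counts.alt_counts, self.counts.depth, pi).sum()
                matches = (np.array(h) == mat[z]).sum()
                weights[(z, h)] = np.exp(ll) * (1 - mu) ** matches * mu ** (3 - matches)
        norm = sum(weights.values())
        oracle = {k: v / norm for k, v in weights.items()}

        rng = np.random.default_rng(42)
        titres = np.log(self.w)
        n = 20_000
        seen = {}
        for _ in range(n):
            state = eng.EngineState(
                titres.copy(),
                np.vstack([other, [0, 0, 0]]).astype(np.int8),
                np.zeros(2, np.int64),
            )
            state = eng.update_haplotype(state, 1, lik, mat, cfg, rng)
            key = (int(state.donors[1]), tuple(int(x) for x in state.haplotypes[1]))
            seen[key] = seen.get(key, 0) + 1

        for key, p in oracle.items():
            if p < 1e-4:
                continue
            se = np.sqrt(p * (1 - p) / n)
            assert abs(seen.get(key, 0) / n - p) < 3 * se + 1e-3

    def test_pair_block_draw_matches_joint_posterior(self):
        """update_haplotype_pair samples (h_1, h_2) from the joint conditional."""
        cfg, mat = self.cfg, self.panel_matrix
        lik = eng._Likelihood(self.counts, cfg)
        oracle = _enumerate_joint(self.counts, mat, self.w, cfg)

        rng = np.random.default_rng(7)
        titres = np.log(self.w)
        n = 20_000
        seen = {}
        state = eng.EngineState(
            titres.copy(), mat.copy()[[0, 1]], np.zeros(2, np.int64)
        )
        for _ in range(n):
            state = eng.update_haplotype_pair(state, (0, 1), lik, mat, cfg, rng)
            key = (
                tuple(int(x) for x in state.haplotypes[0]),
                tuple(int(x) for x in state.haplotypes[1]),
            )
            seen[key] = seen.get(key, 0) + 1

        tv = 0.5 * sum(
            abs(seen.get(k, 0) / n - p) for k, p in oracle.items()
        )
        assert tv < 0.05

    def test_uninformative_emission_follows_likelihood_alone(self):
        """At miscopy 0.5 the donor is irrelevant: allele draw tracks data."""
        cfg = mp.EngineConfig(seed=0, miscopy_rate=0.499)
        counts = _counts([0], [100])  # overwhelming alt evidence
        lik = eng._Likelihood(counts, cfg)
        mat = np.array([[0]], dtype=np.int8)  # donor carries ref
        rng = np.random.default_rng(1)
        draws = []
        for _ in range(200):
            state = eng.EngineState(np.zeros(1), np.array([[0]], np.int8),
                                    np.zeros(1, np.int64))
            state = eng.update_haplotype(state, 0, lik, mat, cfg, rng)
            draws.append(int(state.haplotypes[0, 0]))
        assert np.mean(draws) > 0.99


class TestRunMcmc:
    def test_recovers_both_haplotypes_when_panel_contains_truth(self, small_suite):
        truth = next(t for t in small_suite.mixtures if t.spec.ratio == (4, 1))
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        res = mp.run_mcmc(truth.counts, panel, mp.EngineConfig(seed=2, n_steps=800))
        rec = mp.paired_distance(
            (truth.true_major, truth.true_minor),
            (mp.Haplotype("a", res.haplotypes[0]), mp.Haplotype("b", res.haplotypes[1])),
        )
        assert rec.total == 0
        assert res.proportions[0] == pytest.approx(0.8, abs=0.03)

    def test_single_source_run_with_k1(self, small_suite):
        hap = small_suite.sources[0]
        counts = mp.make_mixture(
            mp.MixtureSpec(hap, hap, (1, 1), 100), small_suite.loci
        )
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        res = mp.run_mcmc(counts, panel, mp.EngineConfig(k=1, seed=0, n_steps=400))
        assert res.proportions == pytest.approx([1.0])
        assert (res.haplotypes[0] == hap.alleles).all()

    def test_seeded_determinism(self, small_suite):
        truth = small_suite.mixtures[0]
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        cfg = mp.EngineConfig(seed=99, n_steps=300)
        r1 = mp.run_mcmc(truth.counts, panel, cfg)
        r2 = mp.run_mcmc(truth.counts, panel, cfg)
        assert (r1.trace == r2.trace).all()
        assert (r1.haplotypes == r2.haplotypes).all()
        assert (r1.proportions == r2.proportions).all()

    def test_proportions_stay_on_simplex(self, small_suite):
        truth = small_suite.mixtures[0]
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        res = mp.run_mcmc(truth.counts, panel, mp.EngineConfig(seed=4, n_steps=300))
        sums = res.proportion_trace.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert (res.proportion_trace > 0).all()

    def test_too_few_retained_samples_rejected(self, small_suite):
        truth = small_suite.mixtures[0]
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        with pytest.raises(ValueError, match="post-burn-in"):
            mp.run_mcmc(truth.counts, panel, mp.EngineConfig(n_steps=2))

    def test_panel_universe_mismatch_rejected(self, small_suite):
        truth = small_suite.mixtures[0]
        panel = mp.ReferencePanel(toy_haplotypes([[0, 1]]))
        with pytest.raises(ValueError, match="universe"):
            mp.run_mcmc(truth.counts, panel, mp.EngineConfig(seed=0))


class TestDiagnostics:
    def test_constant_trace_converges(self):
        res = _result([0.8, 0.2], trace=np.full(200, -50.0))
        z, ok = mp.diagnostics(res)
        assert z == 0.0 and ok

    def test_trending_trace_flagged(self):
        res = _result([0.8, 0.2], trace=np.linspace(-500, -100, 200)
                      + np.random.default_rng(0).normal(0, 1, 200))
        z, ok = mp.diagnostics(res)
        assert abs(z) > 2 and not ok

    def test_default_runs_usually_converge(self, small_suite):
        truth = next(t for t in small_suite.mixtures if t.spec.ratio == (2, 1))
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        flags = []
        for seed in range(8):
            res = mp.run_mcmc(truth.counts, panel,
                              mp.EngineConfig(seed=seed, n_steps=600))
            flags.append(res.converged)
        assert sum(flags) >= 7


class TestEffectiveContributors:
    def test_threshold_counting(self):
        assert mp.effective_contributors(_result([0.8, 0.2]), 0.01) == 2
        assert mp.effective_contributors(_result([0.995, 0.005]), 0.01) == 1

    def test_k2_run_on_single_source_detects_one(self, small_suite):
        hap = small_suite.sources[0]
        counts = mp.make_mixture(mp.MixtureSpec(hap, hap, (1, 1), 100), small_suite.loci)
        panel = mp.ReferencePanel(small_suite.haplotypes, "panel1")
        res = mp.run_mcmc(counts, panel, mp.EngineConfig(k=2, seed=1, n_steps=1000))
        assert mp.effective_contributors(res, 0.01) <= 2  # both strains share one source
        # the modal haplotypes both equal the single source
        assert (res.haplotypes == hap.alleles).all()
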