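"""MCMC deconvolution of haploid mixtures under a panel copying prior.

The observed data are per-site alternative/reference read counts from a
mixture of K haploid contributors.  The model:

* proportions ``w`` live on the simplex via a softmax of Gaussian "titres"
  ``t_k ~ Normal(0, sigma_t^2)``, updated by a Metropolis–Hastings random
  walk;
* each contributor haplotype ``h_k`` is an imperfect copy of a single
  reference-panel member (the Li–Stephens mosaic degenerates to one donor
  because mtDNA does not recombine; the recombination rate is fixed at 0):
  donor ``z_k`` is uniform over the panel and each allele matches the donor
  with probability ``1 - mu`` (mis-copying rate ``mu``);
* read counts are binomial: ``alt_j ~ Binomial(n_j, pi_j)`` with
  ``pi_j = q_j (1 - e) + (1 - q_j) e``, where ``q_j = sum_k w_k h_kj`` is the
  within-sample alternative-allele fraction and ``e`` the per-read error
  rate.  A beta-binomial over-dispersion option is available but off by
  default, since exact in silico counts are binomial-consistent.

Because the copying prior has a single donor per contributor, ``(z_k, h_k)``
admits an exact block-Gibbs draw: donor weights integrate over both alleles
at every site, then alleles are drawn independently given the donor.  All
probability products are accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.special import betaln, gammaln

from .empop import SiteCountTable
from .panels import ReferencePanel

# floor for a single log-probability term, guarding e = 0 degeneracies
_LOG_FLOOR = -745.0


@dataclass
class EngineConfig:
    """Tunable parameters of the deconvolution engine.

    ``k`` contributors (1..5), ``n_steps`` MCMC sweeps with the first
    ``burn_in_fraction`` discarded, per-read miscall probability
    ``read_error``, copying-emission mismatch probability ``miscopy_rate``,
    titre prior scale ``titre_sd``, titre random-walk proposal scale
    ``proposal_sd``, and the posterior-proportion threshold
    ``proportion_floor`` below which a contributor is not counted as
    detected.  ``overdispersion`` switches the read-count likelihood to a
    beta-binomial with that concentration parameter.
    """

    k: int = 2
    n_steps: int = 3000
    burn_in_fraction: float = 0.5
    read_error: float = 0.01
    miscopy_rate: float = 0.01
    recombination_rate: float = 0.0
    titre_sd: float = 3.0
    proposal_sd: float = 0.1
    proportion_floor: float = 0.01
    seed: int = 0
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 5:
            raise ValueError("k must be between 1 and 5")
        if not 0.0 <= self.read_error < 0.5:
            raise ValueError("read_error must be in [0, 0.5)")
        if not 0.0 < self.miscopy_rate < 0.5:
            raise ValueError("miscopy_rate must be in (0, 0.5)")
        if self.recombination_rate != 0.0:
            raise ValueError("only recombination_rate = 0 is supported for mtDNA")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass
class EngineState:
    """Current MCMC state: titres, haplotype matrix, donors, log posterior."""

    titres: np.ndarray          # (K,)
    haplotypes: np.ndarray      # (K, M) int8
    donors: np.ndarray          # (K,) panel row indices
    log_posterior: float = np.nan

    @property
    def proportions(self) -> np.ndarray:
        t = self.titres - self.titres.max()
        e = np.exp(t)
        return e / e.sum()


@dataclass
class DeconvolutionResult:
    """Posterior summaries of one deconvolution run.

    Contributors are ordered by decreasing posterior-mean proportion, so row
    0 is the inferred major.  ``allele_posteriors[k, j]`` is the posterior
    probability that contributor k carries the alternative allele at site j;
    ``haplotypes`` thresholds it at 0.5.
    """

    proportions: np.ndarray        # (K,) posterior means, descending
    haplotypes: np.ndarray         # (K, M) modal alleles
    allele_posteriors: np.ndarray  # (K, M)
    trace: np.ndarray              # (n_steps,) log posterior per sweep
    proportion_trace: np.ndarray   # (n_steps, K) unsorted per-sweep proportions
    acceptance_rate: float
    geweke_z: float
    converged: bool
    n_kept: int
    config: EngineConfig


class _Likelihood:
    """Precomputed pieces of the read-count log likelihood for one mixture."""

    def __init__(self, counts: SiteCountTable, cfg: EngineConfig):
        self.n = counts.depth.astype(np.float64)
        self.a = counts.alt_counts.astype(np.float64)
        self.observed = self.n > 0
        self.e = cfg.read_error
        self.rho = cfg.overdispersion
        if self.rho is None:
            # binomial coefficient is constant across the chain
            self.logcomb = np.where(
                self.observed,
                gammaln(self.n + 1) - gammaln(self.a + 1) - gammaln(self.n - self.a + 1),
                0.0,
            )

    def site_loglik(self, q: np.ndarray) -> np.ndarray:
        """Per-site log P(alt count | allele fraction q); 0 at zero depth."""
        pi = np.clip(q * (1.0 - self.e) + (1.0 - q) * self.e, 1e-300, 1.0 - 1e-16)
        if self.rho is None:
            ll = self.logcomb + self.a * np.log(pi) + (self.n - self.a) * np.log1p(-pi)
        else:
            s = self.rho
            alpha, beta = pi * s, (1.0 - pi) * s
            ll = (
                gammaln(self.n + 1)
                - gammaln(self.a + 1)
                - gammaln(self.n - self.a + 1)
                + betaln(self.a + alpha, self.n - self.a + beta)
                - betaln(alpha, beta)
            )
        ll = np.maximum(ll, _LOG_FLOOR)
        return np.where(self.observed, ll, 0.0)

    def total(self, w: np.ndarray, haplotypes: np.ndarray) -> float:
        q = w @ haplotypes
        return float(self.site_loglik(q).sum())


def log_likelihood(
    w: np.ndarray,
    haplotypes: np.ndarray,
    counts: SiteCountTable,
    cfg: EngineConfig = EngineConfig(),
) -> float:
    """Binomial read-count log likelihood of proportions + haplotypes."""
    w = np.asarray(w, dtype=np.float64)
    haplotypes = np.atleast_2d(np.asarray(haplotypes, dtype=np.float64))
    if w.size != haplotypes.shape[0] or haplotypes.shape[1] != len(counts):
        raise ValueError("inconsistent dimensions")
    return _Likelihood(counts, cfg).total(w, haplotypes)


def _titre_logprior(titres: np.ndarray, sd: float) -> float:
    return float(-0.5 * np.sum((titres / sd) ** 2))


def update_proportions(
    state: EngineState,
    lik: _Likelihood,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> tuple[EngineState, bool]:
    """One Metropolis–Hastings random-walk update of all titres jointly."""
    proposal = state.titres + rng.normal(0.0, cfg.proposal_sd, size=state.titres.size)
    h = state.haplotypes.astype(np.float64)
    cur = lik.total(state.proportions, h) + _titre_logprior(state.titres, cfg.titre_sd)
    t_new = replace(state, titres=proposal)
    new = lik.total(t_new.proportions, h) + _titre_logprior(proposal, cfg.titre_sd)
    if np.log(rng.random()) < new - cur:
        t_new.log_posterior = new
        return t_new, True
    state.log_posterior = cur
    return state, False


def update_proportions_independence(
    state: EngineState,
    lik: _Likelihood,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> tuple[EngineState, bool]:
    """Independence MH update: titres proposed fresh from their prior.

    The acceptance ratio reduces to the likelihood ratio (prior and
    proposal cancel), so the move is almost always rejected when the
    proportions are well identified, but mixes freely when the likelihood
    is flat in ``w`` — the label-degenerate regime of extreme ratios, where
    both strains carry the same haplotype and the random walk alone takes
    arbitrarily long to traverse the proportion space.
    """
    proposal = rng.normal(0.0, cfg.titre_sd, size=state.titres.size)
    h = state.haplotypes.astype(np.float64)
    cur = lik.total(state.proportions, h)
    t_new = replace(state, titres=proposal)
    new = lik.total(t_new.proportions, h)
    if np.log(rng.random()) < new - cur:
        return t_new, True
    return state, False


def _sample_log_categorical(log_weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to exp(log_weights) (any shape, flattened)."""
    flat = log_weights.ravel()
    w = np.exp(flat - flat.max())
    cdf = np.cumsum(w)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right").clip(0, flat.size - 1))


def _lse_rows(stack: np.ndarray) -> np.ndarray:
    """log-sum-exp over axis 0 of a (rows, M) stack, without scipy overhead."""
    m = stack.max(axis=0)
    return m + np.log(np.exp(stack - m).sum(axis=0))


def update_haplotype(
    state: EngineState,
    k: int,
    lik: _Likelihood,
    panel_matrix: np.ndarray,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> EngineState:
    """Exact block-Gibbs draw of (donor, haplotype) for contributor k.

    Conditional on the other contributors, each site has two likelihood
    values (allele 0/1).  A donor's weight is the product over sites of the
    emission-weighted sum of the two, the donor is drawn from those weights
    (uniform prior over the panel), and alleles are then sampled
    independently per site given the donor.
    """
    if panel_matrix.shape[0] == 0:
        raise ValueError("empty reference panel")
    w = state.proportions
    h = state.haplotypes.astype(np.float64)
    q_other = w @ h - w[k] * h[k]

    l0 = lik.site_loglik(q_other)            # allele 0 for strain k
    l1 = lik.site_loglik(q_other + w[k])     # allele 1

    log_match, log_miss = np.log1p(-cfg.miscopy_rate), np.log(cfg.miscopy_rate)
    # site scores given a donor carrying allele 0 (s0) or allele 1 (s1)
    s0 = np.logaddexp(log_match + l0, log_miss + l1)
    s1 = np.logaddexp(log_match + l1, log_miss + l0)

    p = panel_matrix.astype(np.float64)
    log_w_donor = p @ s1 + (1.0 - p) @ s0
    z = _sample_log_categorical(log_w_donor, rng)

    donor = panel_matrix[z].astype(np.float64)
    logit = (l1 - l0) + (2.0 * donor - 1.0) * (log_match - log_miss)
    p_alt = 1.0 / (1.0 + np.exp(-np.clip(logit, -700.0, 700.0)))
    new_h = state.haplotypes.copy()
    new_h[k] = (rng.random(p_alt.size) < p_alt).astype(np.int8)
    new_z = state.donors.copy()
    new_z[k] = z
    return replace(state, haplotypes=new_h, donors=new_z)


def update_haplotype_pair(
    state: EngineState,
    pair: tuple[int, int],
    lik: _Likelihood,
    panel_matrix: np.ndarray,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> EngineState:
    """Exact joint block-Gibbs draw of (donors, haplotypes) for two strains.

    Single-strain updates mode-lock when proportions are near-equal: moving
    a heterozygous site's alternative allele from one strain to the other
    requires both alleles to flip at once, so the He-site partition freezes.
    Because each strain copies a single donor, the joint conditional over
    (z_k, z_l, h_k, h_l) factorizes per site given the donor pair and can be
    sampled exactly: donor-pair weights integrate over all four allele
    combinations at every site, then allele pairs are drawn per site.
    """
    k, l = pair
    w = state.proportions
    h = state.haplotypes.astype(np.float64)
    q_rest = w @ h - w[k] * h[k] - w[l] * h[l]

    # site log likelihoods for the four (allele_k, allele_l) combinations,
    # stacked as rows 0b00, 0b01, 0b10, 0b11 (allele_k is the high bit)
    l_ab = np.stack([
        lik.site_loglik(q_rest + w[k] * a + w[l] * b)
        for a in (0.0, 1.0) for b in (0.0, 1.0)
    ])
    log_match, log_miss = np.log1p(-cfg.miscopy_rate), np.log(cfg.miscopy_rate)
    em = np.array([[log_match, log_miss], [log_miss, log_match]])  # em[a, donor]

    # t[p][r]: per-site score given donor alleles (p, r), alleles summed out
    t = [
        [
            _lse_rows(
                l_ab
                + np.array([em[a, p] + em[b, r] for a in (0, 1) for b in (0, 1)])[:, None]
            )
            for r in (0, 1)
        ]
        for p in (0, 1)
    ]
    # logW[p_donor, r_donor] = sum_j t[P_pj][P_rj][j], decomposed into one
    # matmul plus rank-one broadcasts
    p_mat = panel_matrix.astype(np.float64)
    u = t[1][1] - t[1][0] - t[0][1] + t[0][0]
    log_w_pairs = (
        (p_mat * u) @ p_mat.T
        + (p_mat @ (t[1][0] - t[0][0]))[:, None]
        + (p_mat @ (t[0][1] - t[0][0]))[None, :]
        + t[0][0].sum()
    )
    idx = _sample_log_categorical(log_w_pairs, rng)
    z_k, z_l = divmod(idx, panel_matrix.shape[0])

    donor_k = panel_matrix[z_k]
    donor_l = panel_matrix[z_l]
    # per-site categorical over the four allele pairs given the donor pair
    scores = l_ab + np.stack([
        em[a, donor_k] + em[b, donor_l] for a in (0, 1) for b in (0, 1)
    ])  # (4, M)
    scores -= scores.max(axis=0)
    weights = np.exp(scores)
    cdf = np.cumsum(weights, axis=0)
    cdf /= cdf[-1]
    draw = (rng.random(cdf.shape[1]) < cdf).argmax(axis=0)

    new_h = state.haplotypes.copy()
    new_h[k] = (draw >= 2).astype(np.int8)   # allele_k is the high bit
    new_h[l] = (draw % 2).astype(np.int8)
    new_z = state.donors.copy()
    new_z[k], new_z[l] = z_k, z_l
    return replace(state, haplotypes=new_h, donors=new_z)


def _sweep_haplotypes(
    state: EngineState,
    lik: _Likelihood,
    mat: np.ndarray,
    cfg: EngineConfig,
    rng: np.random.Generator,
) -> EngineState:
    """One haplotype-update pass: joint pair updates, single update leftover."""
    order = rng.permutation(cfg.k)
    i = 0
    while i + 1 < cfg.k:
        state = update_haplotype_pair(
            state, (int(order[i]), int(order[i + 1])), lik, mat, cfg, rng
        )
        i += 2
    if i < cfg.k:
        state = update_haplotype(state, int(order[i]), lik, mat, cfg, rng)
    return state


def run_mcmc(
    counts: SiteCountTable,
    panel: ReferencePanel,
    cfg: EngineConfig = EngineConfig(),
) -> DeconvolutionResult:
    """Run the full sampler and summarize the posterior.

    Titres start at zero (uniform proportions) and haplotypes as random
    panel rows.  Each sweep performs one proportion update followed by a
    block-Gibbs haplotype update for every contributor in random order.
    After discarding burn-in, contributors are relabelled per sample by
    decreasing proportion; when the top two proportions are within 0.05
    (label switching territory, e.g. 1:1 mixtures) the sampled pair is
    aligned to the running modal haplotypes by minimal Hamming matching
    before accumulation.  Fixed seed implies bit-identical output.
    """
    mat = panel.matrix
    if mat.shape[1] != len(counts):
        raise ValueError("panel and counts not on one site universe")
    n_keep = cfg.n_steps - int(cfg.n_steps * cfg.burn_in_fraction)
    if n_keep < 2:
        raise ValueError("fewer than 2 post-burn-in samples; increase n_steps")

    rng = np.random.default_rng(cfg.seed)
    lik = _Likelihood(counts, cfg)
    m = len(counts)
    state = EngineState(
        titres=np.zeros(cfg.k),
        haplotypes=mat[rng.integers(mat.shape[0], size=cfg.k)].copy(),
        donors=np.zeros(cfg.k, dtype=np.int64),
    )

    trace = np.empty(cfg.n_steps)
    prop_trace = np.empty((cfg.n_steps, cfg.k))
    allele_sums = np.zeros((cfg.k, m))
    kept_props = np.empty((n_keep, cfg.k))
    accepted = 0
    kept = 0
    burn_in = cfg.n_steps - n_keep

    for step in range(cfg.n_steps):
        state, ok = update_proportions(state, lik, cfg, rng)
        accepted += ok
        if rng.random() < 0.1:  # occasional prior-draw jump; see docstring
            state, _ = update_proportions_independence(state, lik, cfg, rng)
        state = _sweep_haplotypes(state, lik, mat, cfg, rng)
        w = state.proportions
        trace[step] = lik.total(w, state.haplotypes.astype(np.float64)) + _titre_logprior(
            state.titres, cfg.titre_sd
        )
        prop_trace[step] = w

        if step >= burn_in:
            order = np.argsort(-w, kind="stable")
            w_sorted = w[order]
            h_sorted = state.haplotypes[order]
            if cfg.k == 2 and kept > 0 and abs(w_sorted[0] - w_sorted[1]) < 0.05:
                modal = (allele_sums / kept) > 0.5
                direct = np.sum(h_sorted[0] != modal[0]) + np.sum(h_sorted[1] != modal[1])
                swapped = np.sum(h_sorted[1] != modal[0]) + np.sum(h_sorted[0] != modal[1])
                if swapped < direct:
                    w_sorted = w_sorted[::-1]
                    h_sorted = h_sorted[::-1]
            allele_sums += h_sorted
            kept_props[kept] = w_sorted
            kept += 1

    allele_post = allele_sums / kept
    # per-slot posterior median, renormalized: robust to transient
    # label-degenerate excursions where proportions become unidentified
    proportions = np.median(kept_props[:kept], axis=0)
    proportions = proportions / proportions.sum()
    geweke_z, converged = _geweke(trace[burn_in:])
    return DeconvolutionResult(
        proportions=proportions,
        haplotypes=(allele_post > 0.5).astype(np.int8),
        allele_posteriors=allele_post,
        trace=trace,
        proportion_trace=prop_trace,
        acceptance_rate=accepted / cfg.n_steps,
        geweke_z=geweke_z,
        converged=converged,
        n_kept=kept,
        config=cfg,
    )


def _geweke(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> tuple[float, bool]:
    """Geweke-style level-shift statistic on a log-posterior trace.

    Compares the mean of the first 10% against the last 50%, standardized
    by the trace's marginal standard deviation rather than an iid standard
    error of the means: the proportion random walk gives the log posterior
    long-memory fluctuations, and an iid (or short-lag spectral) standard
    error flags a large fraction of perfectly stationary chains.  With this
    standardization |z| > 2 reads "the early level sits more than two
    trace-widths away from the late level" — the quantitative version of a
    trace plot failing the fuzzy-caterpillar inspection; a drifting or
    stepped chain exceeds it, a noisy stationary chain does not.
    """
    n = trace.size
    a = trace[: max(2, int(n * first))]
    b = trace[-max(2, int(n * last)):]
    if np.ptp(trace) == 0.0:
        return 0.0, True
    z = float((a.mean() - b.mean()) / trace.std(ddof=1))
    return z, abs(z) <= 2.0


def diagnostics(result: DeconvolutionResult) -> tuple[float, bool]:
    """Geweke convergence check on the post-burn-in log-posterior trace.

    Compares the mean of the first 10% against the last 50% of the retained
    trace; |z| > 2 flags a drifting ("non-fuzzy-caterpillar") chain.
    """
    burn_in = result.trace.size - result.n_kept
    if result.trace.size - burn_in < 20:
        raise ValueError("trace too short for diagnostics (need >= 20 retained)")
    return _geweke(result.trace[burn_in:])


def effective_contributors(result: DeconvolutionResult, tau: float | None = None) -> int:
    """Number of contributors with posterior-mean proportion >= tau."""
    if tau is None:
        tau = result.config.proportion_floor
    return int(np.sum(result.proportions >= tau))
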