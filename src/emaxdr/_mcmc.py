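"""Adaptive Metropolis sampling with an independence-proposal booster.

A small, dependency-free MCMC engine used by the study-level meta-analysis.
Each chain mixes two Metropolis kernels:

- a random-walk kernel whose Gaussian proposal is adapted during warmup in
  the style of Haario et al. (2001): the proposal covariance tracks the
  empirical covariance of the history (scaled by 2.38^2 / d) and a global
  step-size factor is tuned toward a target acceptance rate;
- an independence kernel proposing from a multivariate Student-t (df = 6)
  fitted to the second half of the warmup history (falling back to a
  supplied Laplace approximation during warmup), which delivers
  near-independent draws when the posterior is approximately elliptical
  while the random-walk component guarantees local moves everywhere.

Both proposals are frozen at the end of warmup, so the post-warmup chain is
a valid fixed-kernel Metropolis chain.

Reproducibility contract: given the same log-density, initial point and
seed, the draws are bit-identical.  Chains are seeded from independent
``numpy.random.SeedSequence`` spawns.
"""

from __future__ import annotations

import numpy as np

__all__ = ["run_chains"]

_T_DF = 6.0
_P_INDEP = 0.8


class _TProposal:
    """Multivariate Student-t proposal with cached Cholesky pieces."""

    def __init__(self, mean, cov, df=_T_DF, inflate=1.3):
        self.mean = np.asarray(mean, float)
        self.df = df
        cov = inflate * np.asarray(cov, float) \
            + 1e-10 * np.eye(self.mean.size)
        self.chol = np.linalg.cholesky(cov)  # may raise LinAlgError
        self._logdet = 2.0 * np.sum(np.log(np.diag(self.chol)))

    def sample(self, rng):
        d = self.mean.size
        z = rng.standard_normal(d)
        w = rng.chisquare(self.df)
        return self.mean + (self.chol @ z) * np.sqrt(self.df / w)

    def logpdf(self, x):
        d = self.mean.size
        u = np.linalg.solve(self.chol, x - self.mean)
        m = u @ u
        return (-0.5 * (self.df + d) * np.log1p(m / self.df)
                - 0.5 * self._logdet)


def _run_single_chain(logpost, x0, n_warmup, n_draws, rng, target_accept,
                      chol0=None, indep0=None):
    d = x0.size
    x = x0.astype(float).copy()
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior not finite at initial point")

    log_scale = 0.0
    rw_chol = np.eye(d) if chol0 is None else chol0.copy()
    indep = indep0
    history = np.empty((n_warmup, d))
    accepted = 0
    window = 0

    total = n_warmup + n_draws
    draws = np.empty((n_draws, d))
    n_accept_post = 0

    for t in range(total):
        use_indep = indep is not None and rng.random() < _P_INDEP
        if use_indep:
            prop = indep.sample(rng)
            lp_prop = logpost(prop)
            log_alpha = (lp_prop - lp
                         + indep.logpdf(x) - indep.logpdf(prop))
        else:
            step = np.exp(log_scale) * (rw_chol @ rng.standard_normal(d))
            prop = x + step
            lp_prop = logpost(prop)
            log_alpha = lp_prop - lp
        if np.log(rng.random()) < log_alpha:
            x, lp = prop, lp_prop
            if not use_indep:
                accepted += 1
            if t >= n_warmup:
                n_accept_post += 1
        if t < n_warmup:
            history[t] = x
            if not use_indep:
                window += 1
            # adapt every 25 steps: random-walk step size toward the target
            # acceptance, proposal shape toward the history covariance
            if (t + 1) % 25 == 0:
                if window:
                    rate = accepted / window
                    log_scale += (rate - target_accept) \
                        / np.sqrt((t + 1) / 25.0)
                accepted = 0
                window = 0
                if t + 1 >= 200:
                    emp = np.cov(history[: t + 1].T).reshape(d, d)
                    emp = (2.38**2 / d) * emp + 1e-8 * np.eye(d)
                    try:
                        rw_chol = np.linalg.cholesky(emp)
                        log_scale = 0.0
                    except np.linalg.LinAlgError:
                        pass
            if t + 1 == n_warmup:
                # freeze: refit the independence proposal to the second
                # half of warmup (falls back to the warmup proposal)
                half = history[n_warmup // 2:]
                try:
                    indep = _TProposal(half.mean(axis=0),
                                       np.cov(half.T).reshape(d, d))
                except np.linalg.LinAlgError:
                    pass
        else:
            draws[t - n_warmup] = x

    accept_rate = n_accept_post / max(n_draws, 1)
    return draws, accept_rate


def run_chains(logpost, x0, *, n_chains, n_warmup, n_draws, seed,
               target_accept=0.3, jitter=1.0, prop_chol=None):
    """Run independent adaptive-Metropolis chains.

    Parameters
    ----------
    logpost : callable
        Log posterior density on the (unconstrained) sampling space.
    x0 : array (d,)
        Common starting point; each chain starts from a jittered copy
        (chain 0 starts exactly at ``x0``).
    n_chains, n_warmup, n_draws : int
        Chain count and per-chain lengths.
    seed : int
        Master seed; chains use independent spawned substreams.
    prop_chol : array (d, d), optional
        Cholesky factor of an initial proposal covariance (e.g. a Laplace
        approximation at the mode); shapes the initial random walk, the
        warmup-phase independence proposal and the start jitter.

    Returns
    -------
    draws : array (n_chains, n_draws, d)
    accept_rates : array (n_chains,)
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    d = x0.size
    chol0 = None
    indep0 = None
    if prop_chol is not None:
        prop_chol = np.asarray(prop_chol, float)
        chol0 = np.sqrt(2.38**2 / d) * prop_chol
        try:
            indep0 = _TProposal(x0, prop_chol @ prop_chol.T, inflate=2.0)
        except np.linalg.LinAlgError:
            indep0 = None
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    draws = np.empty((n_chains, n_draws, d))
    rates = np.empty(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(children[c])
        scale_chol = chol0 if chol0 is not None else np.eye(d)
        start = x0 if c == 0 else \
            x0 + jitter * (scale_chol @ rng.standard_normal(d))
        # nudge a non-finite jittered start back toward x0
        tries = 0
        while not np.isfinite(logpost(start)) and tries < 50:
            start = x0 + jitter * 0.5 ** (tries + 1) \
                * (scale_chol @ rng.standard_normal(d))
            tries += 1
        draws[c], rates[c] = _run_single_chain(
            logpost, start, n_warmup, n_draws, rng, target_accept,
            chol0=chol0, indep0=indep0,
        )
    return draws, rates
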