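"""Bayesian hierarchical Emax meta-analysis of study-level FEV1 contrasts.

The observation unit is a least-squares-mean (LSM) contrast to placebo in
trough FEV1 (mL) with its standard error, one row per study x treatment-arm
x steady-state visit.  The bronchodilator arms follow a hierarchical Emax
curve with between-study (delta_i) and within-study between-visit (gamma_ij)
random effects on Emax; comparator arms contribute treatment-specific means
(salmeterol additionally carries a visit-level random effect).  For an
indacaterol arm of study i at visit j with dose d,

    y_ij ~ Normal((Emax + delta_i + gamma_ij) * d / (ED50 + d), se_ij^2)
    delta_i ~ N(0, omega_study^2),   gamma_ij ~ N(0, omega_visit^2)

and the placebo response is structurally zero because the data are contrasts.
Reported SEs are taken as known observation SDs.  Because the model is
linear and Gaussian in the random effects given (Emax, ED50, omegas), the
random effects are marginalised analytically and MCMC runs on the eight
structural parameters only.

The public surface follows the statsmodels pattern:
``StudyLevelEmaxModel(data).fit(McmcConfig(...))`` returns a
:class:`StudyLevelEmaxResults` with ``summary()``, ``prob_exceeds()``,
``predict_curve()`` and ``rank_treatments()``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _mcmc
from .core import DoseGrid, dose_for_fraction

__all__ = [
    "StudyLevelParams",
    "Prior",
    "PriorSpec",
    "default_priors",
    "McmcConfig",
    "PosteriorSamples",
    "validate_study_data",
    "log_posterior_density",
    "StudyLevelEmaxModel",
    "StudyLevelEmaxResults",
]

TREATMENTS = ("indacaterol", "formoterol", "salmeterol", "tiotropium")

PARAM_NAMES = (
    "emax",
    "ed50",
    "omega_study",
    "omega_visit",
    "mu_for",
    "mu_sal",
    "omega_sal_visit",
    "mu_tio",
)
_POSITIVE = frozenset({"ed50", "omega_study", "omega_visit", "omega_sal_visit"})

REQUIRED_COLUMNS = ("study_id", "treatment", "dose_ug", "visit_id",
                    "lsm_contrast_ml", "se_ml")


@dataclass(frozen=True)
class StudyLevelParams:
    """Structural parameters of the study-level model (mL / μg units)."""

    emax: float
    ed50: float
    omega_study: float
    omega_visit: float
    mu_for: float = 0.0
    mu_sal: float = 0.0
    omega_sal_visit: float = 0.0
    mu_tio: float = 0.0

    def __post_init__(self):
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        for name in ("omega_study", "omega_visit", "omega_sal_visit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], float)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """One marginal prior: family in {normal, lognormal, halfnormal,
    uniform, point} with its hyperparameters ``args``.

    ``lognormal(mu, sd)`` parameterises the log; ``halfnormal(sd)`` is the
    positive half of N(0, sd^2); ``point(value)`` fixes the parameter (it is
    excluded from sampling and the posterior is a point mass).
    """

    family: str
    args: tuple

    def logpdf(self, x: float) -> float:
        a = self.args
        if self.family == "normal":
            mu, sd = a
            return -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((x - mu) / sd) ** 2
        if self.family == "lognormal":
            if x <= 0:
                return -np.inf
            mu, sd = a
            lx = np.log(x)
            return (-0.5 * np.log(2 * np.pi * sd**2) - lx
                    - 0.5 * ((lx - mu) / sd) ** 2)
        if self.family == "halfnormal":
            (sd,) = a
            if x < 0:
                return -np.inf
            return (0.5 * np.log(2 / (np.pi * sd**2))
                    - 0.5 * (x / sd) ** 2)
        if self.family == "uniform":
            lo, hi = a
            return -np.log(hi - lo) if lo <= x <= hi else -np.inf
        if self.family == "point":
            raise TypeError("point priors have no density")
        raise ValueError(f"unknown prior family {self.family!r}")

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def typical(self) -> float:
        """A central value used to initialise the sampler."""
        a = self.args
        if self.family == "normal":
            return a[0]
        if self.family == "lognormal":
            return float(np.exp(a[0]))
        if self.family == "halfnormal":
            return 0.5 * a[0]
        if self.family == "uniform":
            return 0.5 * (a[0] + a[1])
        if self.family == "point":
            return a[0]
        raise ValueError(self.family)


PriorSpec = dict  # mapping param name -> Prior


def default_priors() -> PriorSpec:
    """Weakly informative defaults covering every structural parameter.

    Effects (mL) get Normal(0, 500^2); ED50 gets a diffuse lognormal centred
    at 100 μg; variability SDs get Half-Normal(100 mL).  All overridable by
    passing a modified mapping to the model.
    """
    return {
        "emax": Prior("normal", (0.0, 500.0)),
        "ed50": Prior("lognormal", (np.log(100.0), 2.0)),
        "omega_study": Prior("halfnormal", (100.0,)),
        "omega_visit": Prior("halfnormal", (100.0,)),
        "mu_for": Prior("normal", (0.0, 500.0)),
        "mu_sal": Prior("normal", (0.0, 500.0)),
        "omega_sal_visit": Prior("halfnormal", (100.0,)),
        "mu_tio": Prior("normal", (0.0, 500.0)),
    }


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: chain count/lengths, seed and target acceptance."""

    n_chains: int = 4
    n_warmup: int = 1500
    n_draws: int = 1500
    seed: int = 0
    target_acceptance: float = 0.3

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_draws <= 0 or self.n_warmup < 0:
            raise ValueError("chain lengths must be positive")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_VISIT_RE = re.compile(r"^\s*(week|wk|month|mo|day)\s*(\d+(?:\.\d+)?)\s*$",
                       re.IGNORECASE)
_WEEKS_PER_MONTH = 52.0 / 12.0
_VISIT_WINDOW_WEEKS = (2.0, 6.0 * _WEEKS_PER_MONTH + 1e-9)


def parse_visit_weeks(visit_id) -> float | None:
    """Parse a visit label ('Week 2', 'Month 6', 'Day 84') into weeks."""
    m = _VISIT_RE.match(str(visit_id))
    if not m:
        return None
    unit, value = m.group(1).lower(), float(m.group(2))
    if unit in ("week", "wk"):
        return value
    if unit in ("month", "mo"):
        return value * _WEEKS_PER_MONTH
    return value / 7.0


def validate_study_data(rows: pd.DataFrame):
    """Validate study-level rows; return (validated table, rejection log).

    Rules, each logged per offending row:

    - ``missing_column`` raised immediately (structural defect);
    - ``nonpositive_se``: se must be > 0 and finite;
    - ``unknown_treatment``: treatment must be one of indacaterol /
      formoterol / salmeterol / tiotropium (case-insensitive);
    - ``missing_dose``: indacaterol rows need a positive dose;
    - ``nonfinite_contrast``: LSM contrast must be finite;
    - ``visit_outside_window``: visits must parse and land in the
      steady-state window [Week 2, Month 6].

    Raises ValueError on empty input or when every row is rejected.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("study-level table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"study-level table lacks columns {missing}")

    df = rows.copy().reset_index(drop=True)
    df["treatment"] = df["treatment"].astype(str).str.strip().str.lower()
    rejections = []

    def reject(mask, rule, detail):
        for idx in df.index[mask]:
            rejections.append(
                {"row": int(idx), "study_id": df.at[idx, "study_id"],
                 "rule": rule, "detail": detail}
            )
        return mask

    se = pd.to_numeric(df["se_ml"], errors="coerce")
    bad = reject(~(se > 0) | ~np.isfinite(se), "nonpositive_se",
                 "se_ml must be a positive finite number")
    bad |= reject(~df["treatment"].isin(TREATMENTS) & ~bad,
                  "unknown_treatment",
                  f"treatment must be one of {TREATMENTS}")
    dose = pd.to_numeric(df["dose_ug"], errors="coerce")
    bad |= reject((df["treatment"] == "indacaterol") & ~(dose > 0) & ~bad,
                  "missing_dose", "indacaterol rows require dose_ug > 0")
    y = pd.to_numeric(df["lsm_contrast_ml"], errors="coerce")
    bad |= reject(~np.isfinite(y) & ~bad, "nonfinite_contrast",
                  "lsm_contrast_ml must be finite")
    weeks = df["visit_id"].map(parse_visit_weeks)
    in_window = weeks.notna() & (weeks >= _VISIT_WINDOW_WEEKS[0]) \
        & (weeks <= _VISIT_WINDOW_WEEKS[1])
    bad |= reject(~in_window & ~bad, "visit_outside_window",
                  "visit must parse and lie within [Week 2, Month 6]")

    log = pd.DataFrame(rejections,
                       columns=["row", "study_id", "rule", "detail"])
    valid = df.loc[~bad].reset_index(drop=True)
    if len(valid) == 0:
        raise ValueError("every study-level row was rejected:\n"
                         + log.to_string(index=False))
    valid["dose_ug"] = pd.to_numeric(valid["dose_ug"], errors="coerce")
    valid["lsm_contrast_ml"] = pd.to_numeric(valid["lsm_contrast_ml"])
    valid["se_ml"] = pd.to_numeric(valid["se_ml"])
    return valid, log


# ---------------------------------------------------------------------------
# joint density with explicit random effects (reference form)
# ---------------------------------------------------------------------------

def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((x - mu) / sd) ** 2


def log_posterior_density(params: StudyLevelParams, random_effects: dict,
                          data: pd.DataFrame, priors: PriorSpec | None = None,
                          gamma_shared_within_visit: bool = False) -> float:
    """Joint log posterior with random effects explicit (not marginalised).

    ``random_effects`` maps:

    - ``"delta"`` -> array over the distinct indacaterol studies, in order
      of first appearance in ``data``;
    - ``"gamma"`` -> array over indacaterol rows in data order (default), or
      over distinct (study, visit) pairs in order of first appearance when
      ``gamma_shared_within_visit`` is True;
    - ``"gamma_sal"`` -> array over salmeterol rows in data order.

    The value is the sum of the observation log-likelihood (each contrast
    normal about its arm mean with SD = reported se), the random-effect
    log-densities, and the log-priors on the structural parameters (omit
    ``priors`` for a flat-prior/likelihood evaluation).  Used as the ground
    truth against which the marginalised likelihood is verified.
    """
    p = params
    arr = p.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite structural parameters")

    ind = data[data["treatment"] == "indacaterol"]
    sal = data[data["treatment"] == "salmeterol"]
    for_ = data[data["treatment"] == "formoterol"]
    tio = data[data["treatment"] == "tiotropium"]

    studies = list(dict.fromkeys(ind["study_id"]))
    delta = np.atleast_1d(np.asarray(random_effects.get("delta", np.zeros(len(studies))), float))
    if delta.size != len(studies):
        raise ValueError(f"delta has size {delta.size}, expected {len(studies)}")
    if gamma_shared_within_visit:
        groups = list(dict.fromkeys(zip(ind["study_id"], ind["visit_id"])))
        gamma = np.atleast_1d(np.asarray(random_effects.get("gamma", np.zeros(len(groups))), float))
        if gamma.size != len(groups):
            raise ValueError(f"gamma has size {gamma.size}, expected {len(groups)}")
        gamma_row = np.array([gamma[groups.index((s, v))]
                              for s, v in zip(ind["study_id"], ind["visit_id"])])
    else:
        gamma = np.atleast_1d(np.asarray(random_effects.get("gamma", np.zeros(len(ind))), float))
        if gamma.size != len(ind):
            raise ValueError(f"gamma has size {gamma.size}, expected {len(ind)}")
        gamma_row = gamma
    gamma_sal = np.atleast_1d(np.asarray(random_effects.get("gamma_sal", np.zeros(len(sal))), float))
    if gamma_sal.size != len(sal):
        raise ValueError(f"gamma_sal has size {gamma_sal.size}, expected {len(sal)}")

    delta_row = np.array([delta[studies.index(s)] for s in ind["study_id"]])
    frac = ind["dose_ug"].to_numpy() / (p.ed50 + ind["dose_ug"].to_numpy())
    mean_ind = (p.emax + delta_row + gamma_row) * frac

    ll = _norm_logpdf(ind["lsm_contrast_ml"].to_numpy(), mean_ind,
                      ind["se_ml"].to_numpy()).sum()
    ll += _norm_logpdf(sal["lsm_contrast_ml"].to_numpy(),
                       p.mu_sal + gamma_sal, sal["se_ml"].to_numpy()).sum()
    ll += _norm_logpdf(for_["lsm_contrast_ml"].to_numpy(), p.mu_for,
                       for_["se_ml"].to_numpy()).sum()
    ll += _norm_logpdf(tio["lsm_contrast_ml"].to_numpy(), p.mu_tio,
                       tio["se_ml"].to_numpy()).sum()

    # random-effect densities (an SD of exactly 0 demands zero effects)
    for vec, sd, label in ((delta, p.omega_study, "delta"),
                           (gamma, p.omega_visit, "gamma"),
                           (gamma_sal, p.omega_sal_visit, "gamma_sal")):
        if vec.size == 0:
            continue
        if sd == 0:
            if np.any(vec != 0):
                return -np.inf
        else:
            ll += _norm_logpdf(vec, 0.0, sd).sum()

    if priors is not None:
        for name in PARAM_NAMES:
            prior = priors[name]
            if not prior.is_point:
                ll += prior.logpdf(getattr(p, name))
    return float(ll)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class StudyLevelEmaxModel:
    """Hierarchical Emax meta-analysis model for study-level LSM contrasts.

    Parameters
    ----------
    data : DataFrame
        Columns study_id, treatment, dose_ug, visit_id, lsm_contrast_ml,
        se_ml (and optionally n).  Rows failing validation are dropped and
        logged on ``self.rejection_log``.
    priors : mapping, optional
        Per-parameter :class:`Prior`; defaults to :func:`default_priors`.
    gamma_shared_within_visit : bool
        Whether the visit-level effect gamma_ij is shared by all indacaterol
        arms observed at the same study-visit (default False: one gamma per
        arm-visit row).
    """

    def __init__(self, data: pd.DataFrame, priors: PriorSpec | None = None,
                 gamma_shared_within_visit: bool = False):
        self.data, self.rejection_log = validate_study_data(data)
        self.priors = dict(default_priors())
        if priors:
            self.priors.update(priors)
        for name in PARAM_NAMES:
            if name not in self.priors:
                raise ValueError(f"no prior for parameter {name!r}")
        self.gamma_shared = bool(gamma_shared_within_visit)
        self._prepare()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StudyLevelEmaxModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- precomputation ----------------------------------------------------
    def _prepare(self):
        df = self.data
        ind = df[df["treatment"] == "indacaterol"]
        # group indacaterol rows contiguously by study for reduceat sums
        codes, _ = pd.factorize(ind["study_id"])
        order = np.argsort(codes, kind="stable")
        ind = ind.iloc[order]
        self._ind_dose = ind["dose_ug"].to_numpy(float)
        self._ind_y = ind["lsm_contrast_ml"].to_numpy(float)
        self._ind_se2 = ind["se_ml"].to_numpy(float) ** 2
        codes = codes[order]
        self._study_starts = np.flatnonzero(
            np.r_[True, np.diff(codes) != 0]) if len(ind) else np.array([], int)
        self._n_studies = int(codes.max()) + 1 if len(ind) else 0
        self._ind_visit_key = list(zip(ind["study_id"], ind["visit_id"]))
        self._ind_index = ind.index.to_numpy()

        for trt, tag in (("salmeterol", "sal"), ("formoterol", "for"),
                         ("tiotropium", "tio")):
            sub = df[df["treatment"] == trt]
            setattr(self, f"_{tag}_y", sub["lsm_contrast_ml"].to_numpy(float))
            setattr(self, f"_{tag}_se2", sub["se_ml"].to_numpy(float) ** 2)

    # -- marginal likelihood ----------------------------------------------
    def loglike(self, params: StudyLevelParams) -> float:
        """Marginal log-likelihood with random effects integrated out.

        Indacaterol studies contribute multivariate normal blocks with
        covariance  omega_study^2 f f' + diag(omega_visit^2 f^2 + se^2)
        (fractions-of-max f), evaluated via the rank-one
        Sherman-Morrison/determinant-lemma identities; salmeterol rows are
        independent with variance omega_sal_visit^2 + se^2.
        """
        p = params
        ll = 0.0
        if self._ind_y.size:
            f = self._ind_dose / (p.ed50 + self._ind_dose)
            if self.gamma_shared:
                ll += self._loglike_ind_shared(p, f)
            else:
                D = p.omega_visit**2 * f**2 + self._ind_se2
                r = self._ind_y - p.emax * f
                st = self._study_starts
                A = np.add.reduceat(f * f / D, st)
                B = np.add.reduceat(f * r / D, st)
                C = np.add.reduceat(r * r / D, st)
                L = np.add.reduceat(np.log(D), st)
                n_s = np.diff(np.r_[st, self._ind_y.size])
                w = p.omega_study**2
                denom = 1.0 + w * A
                logdet = L + np.log(denom)
                quad = C - w * B * B / denom
                ll += -0.5 * float(np.sum(n_s * np.log(2 * np.pi)
                                          + logdet + quad))
        if self._sal_y.size:
            v = p.omega_sal_visit**2 + self._sal_se2
            ll += float(np.sum(-0.5 * (np.log(2 * np.pi * v)
                                       + (self._sal_y - p.mu_sal) ** 2 / v)))
        if self._for_y.size:
            ll += float(_norm_logpdf(self._for_y, p.mu_for,
                                     np.sqrt(self._for_se2)).sum())
        if self._tio_y.size:
            ll += float(_norm_logpdf(self._tio_y, p.mu_tio,
                                     np.sqrt(self._tio_se2)).sum())
        return ll

    def _loglike_ind_shared(self, p: StudyLevelParams, f: np.ndarray) -> float:
        """Dense per-study blocks for the shared-gamma variant."""
        ll = 0.0
        starts = np.r_[self._study_starts, self._ind_y.size]
        keys = self._ind_visit_key
        for s in range(self._n_studies):
            lo, hi = starts[s], starts[s + 1]
            fs = f[lo:hi]
            r = self._ind_y[lo:hi] - p.emax * fs
            cov = (p.omega_study**2) * np.outer(fs, fs) + np.diag(self._ind_se2[lo:hi])
            vis = pd.factorize(pd.Series([k[1] for k in keys[lo:hi]]))[0]
            for v in np.unique(vis):
                m = (vis == v).astype(float) * fs
                cov += (p.omega_visit**2) * np.outer(m, m)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                return -np.inf
            quad = r @ np.linalg.solve(cov, r)
            ll += -0.5 * ((hi - lo) * np.log(2 * np.pi) + logdet + quad)
        return float(ll)

    # -- posterior over the unconstrained sampling space -------------------
    def _free_params(self):
        return [n for n in PARAM_NAMES if not self.priors[n].is_point]

    def _unpack(self, z: np.ndarray) -> StudyLevelParams | None:
        vals = {}
        i = 0
        for name in PARAM_NAMES:
            prior = self.priors[name]
            if prior.is_point:
                vals[name] = prior.args[0]
            else:
                zi = z[i]
                i += 1
                vals[name] = float(np.exp(zi)) if name in _POSITIVE else float(zi)
        if not all(np.isfinite(v) for v in vals.values()):
            return None
        return StudyLevelParams(**vals)

    def _log_posterior_z(self, z: np.ndarray) -> float:
        params = self._unpack(z)
        if params is None:
            return -np.inf
        lp = self.loglike(params)
        i = 0
        for name in PARAM_NAMES:
            prior = self.priors[name]
            if prior.is_point:
                continue
            x = getattr(params, name)
            lp += prior.logpdf(x)
            if name in _POSITIVE:
                lp += z[i]  # Jacobian of x = exp(z)
            i += 1
        return lp if np.isfinite(lp) else -np.inf

    def _start_point(self) -> np.ndarray:
        """Data-informed deterministic start on the z scale."""
        start = {}
        if self._ind_y.size:
            start["emax"] = float(np.clip(np.max(self._ind_y), 10.0, 1000.0))
        start["ed50"] = 50.0
        start["omega_study"] = 20.0
        start["omega_visit"] = 15.0
        start["omega_sal_visit"] = 15.0
        start["mu_sal"] = float(np.mean(self._sal_y)) if self._sal_y.size else 0.0
        start["mu_for"] = float(np.mean(self._for_y)) if self._for_y.size else 0.0
        start["mu_tio"] = float(np.mean(self._tio_y)) if self._tio_y.size else 0.0
        z = []
        for name in self._free_params():
            x = start.get(name, self.priors[name].typical())
            z.append(np.log(x) if name in _POSITIVE else x)
        return np.array(z)

    def _map_and_laplace(self):
        """Posterior mode on the z scale and a Laplace proposal Cholesky.

        Used only to initialise the sampler (start point and initial
        proposal shape); the reported posterior comes from MCMC alone.
        """
        from scipy import optimize

        from ._numdiff import numerical_hessian

        nlp = lambda z: -self._log_posterior_z(z)
        z0 = self._start_point()
        res = optimize.minimize(nlp, z0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-6,
                                         "fatol": 1e-6})
        res = optimize.minimize(nlp, res.x, method="L-BFGS-B")
        z_map = res.x if np.isfinite(res.fun) else z0
        try:
            H = numerical_hessian(nlp, z_map, rel_step=1e-3)
            # symmetrise and regularise to a valid covariance
            H = 0.5 * (H + H.T)
            evals, evecs = np.linalg.eigh(H)
            evals = np.clip(evals, 1e-6, None)
            cov = (evecs / evals) @ evecs.T
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = None
        return z_map, chol

    # -- fitting -----------------------------------------------------------
    def fit(self, config: McmcConfig | None = None) -> "StudyLevelEmaxResults":
        """Sample the posterior by adaptive Metropolis MCMC.

        Chains start from the posterior mode with the local curvature
        (Laplace) covariance as the initial proposal, then adapt during
        warmup.  Reproducible given ``config.seed``.  Warns (does not fail)
        when any split-R-hat reaches 1.01.  With every prior a point mass
        the "posterior" is returned as constant draws without running MCMC.
        """
        config = config or McmcConfig()
        free = self._free_params()
        n_total = config.n_chains * config.n_draws

        if not free:
            arr = np.empty((config.n_chains, config.n_draws, 0))
            samples = self._package(arr, config, accept_rates=np.zeros(config.n_chains))
            return StudyLevelEmaxResults(self, samples)

        z_map, chol = self._map_and_laplace()
        draws_z, rates = _mcmc.run_chains(
            self._log_posterior_z, z_map,
            n_chains=config.n_chains, n_warmup=config.n_warmup,
            n_draws=config.n_draws, seed=config.seed,
            target_accept=config.target_acceptance, prop_chol=chol,
        )
        samples = self._package(draws_z, config, rates)
        assert samples.n_total == n_total
        return StudyLevelEmaxResults(self, samples)

    def _package(self, draws_z, config, accept_rates) -> "PosteriorSamples":
        free = self._free_params()
        n_chains, n_draws, _ = draws_z.shape
        nat = np.empty((n_chains, n_draws, len(PARAM_NAMES)))
        for j, name in enumerate(PARAM_NAMES):
            prior = self.priors[name]
            if prior.is_point:
                nat[:, :, j] = prior.args[0]
            else:
                col = draws_z[:, :, free.index(name)]
                nat[:, :, j] = np.exp(col) if name in _POSITIVE else col
        return PosteriorSamples(nat, PARAM_NAMES, config, accept_rates,
                                point_mask=[self.priors[n].is_point
                                            for n in PARAM_NAMES])


# ---------------------------------------------------------------------------
# posterior container and results
# ---------------------------------------------------------------------------

class PosteriorSamples:
    """Joint MCMC draws of the structural parameters with diagnostics.

    ``array`` has shape (n_chains, n_draws, n_params) on the natural scale;
    ``diagnostics`` holds split-R-hat and bulk ESS per sampled parameter
    (NaN for point-mass parameters, which are constant by construction).
    """

    def __init__(self, array, param_names, config, accept_rates,
                 point_mask=None):
        self.array = np.asarray(array)
        self.param_names = tuple(param_names)
        self.config = config
        self.accept_rates = np.asarray(accept_rates)
        self.point_mask = list(point_mask or [False] * len(self.param_names))
        self.diagnostics = self._diagnose()

    @property
    def n_total(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter pooled across chains, shape (n_total,)."""
        j = self.param_names.index(name)
        return self.array[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_draws, _ = self.array.shape
        df = pd.DataFrame(self.array.reshape(-1, len(self.param_names)),
                          columns=self.param_names)
        df.insert(0, "draw", np.tile(np.arange(n_draws), n_chains))
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config=None) -> "PosteriorSamples":
        """Rebuild a draws container from :meth:`to_frame` output (e.g. a
        draws CSV written by the fit-study pipeline stage)."""
        names = [c for c in df.columns if c not in ("chain", "draw")]
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1
        arr = (df.sort_values(["chain", "draw"])[names].to_numpy()
               .reshape(n_chains, n_draws, len(names)))
        rates = np.full(n_chains, np.nan)
        return cls(arr, names, config, rates)

    def _diagnose(self) -> pd.DataFrame:
        import arviz as az
        rows = []
        for j, name in enumerate(self.param_names):
            if self.point_mask[j] or np.ptp(self.array[:, :, j]) == 0:
                rows.append({"parameter": name, "rhat": np.nan,
                             "ess_bulk": np.nan})
                continue
            col = self.array[:, :, j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append({
                    "parameter": name,
                    "rhat": float(az.rhat(az.convert_to_dataset(col))["x"]),
                    "ess_bulk": float(az.ess(az.convert_to_dataset(col))["x"]),
                })
        df = pd.DataFrame(rows)
        worst = df["rhat"].max()
        if np.isfinite(worst) and worst >= 1.01:
            warnings.warn(
                f"MCMC convergence suspect: max split-R-hat = {worst:.3f} "
                "(threshold 1.01); consider longer chains", RuntimeWarning)
        return df


def _summ(x: np.ndarray) -> dict:
    q = np.percentile(x, [2.5, 50, 97.5])
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2])}


class StudyLevelEmaxResults:
    """Posterior of the study-level meta-analysis with derived quantities.

    ``model`` may be None when the results are rebuilt from stored draws;
    everything except the data-driven default of ``typical_se`` in
    :meth:`predict_curve` still works.
    """

    def __init__(self, model: StudyLevelEmaxModel | None,
                 samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # convenience accessors
    @property
    def emax_draws(self) -> np.ndarray:
        return self.samples.stacked("emax")

    @property
    def ed50_draws(self) -> np.ndarray:
        return self.samples.stacked("ed50")

    def effect_draws(self, dose: float) -> np.ndarray:
        """Per-draw mean improvement over placebo at ``dose`` (mL)."""
        if dose < 0:
            raise ValueError("dose must be nonnegative")
        if dose == 0:
            return np.zeros(self.samples.n_total)
        return self.emax_draws * dose / (self.ed50_draws + dose)

    def summary(self, dose_grid=None) -> pd.DataFrame:
        """Posterior summary table: structural parameters, ED90, and the
        percentage of maximal effect at each grid dose (computed per draw,
        then summarised as mean/sd/2.5%/median/97.5%)."""
        dose_grid = np.asarray(dose_grid if dose_grid is not None
                               else (18.75, 37.5, 75, 150, 300, 600), float)
        rows = {}
        for name in self.samples.param_names:
            rows[name] = _summ(self.samples.stacked(name))
        ed50 = self.ed50_draws
        rows["ED90"] = _summ(dose_for_fraction(0.9, 1.0) * ed50)  # 9 * ED50
        for d in dose_grid:
            if d <= 0:
                continue
            rows[f"pct_max_{d:g}"] = _summ(100.0 * d / (ed50 + d))
        out = pd.DataFrame(rows).T
        out.index.name = "quantity"
        return out

    def prob_exceeds(self, dose: float, threshold: float = 120.0) -> float:
        """Posterior probability that the mean improvement at ``dose``
        exceeds ``threshold`` mL (default: the 120 mL MCID)."""
        return float(np.mean(self.effect_draws(dose) > threshold))

    def predict_curve(self, dose_grid, typical_se: float | None = None,
                      seed: int = 0) -> pd.DataFrame:
        """Dose-response curve with 95% credible and 95% prediction bands.

        The credible band is the per-dose quantile band of the posterior
        mean curve.  The prediction band describes a new study-visit LSM:
        per draw, study- and visit-level effects (scaled by fraction of
        maximum) and observation noise of SD ``typical_se`` are added before
        taking quantiles.  ``typical_se`` defaults to the median reported SE
        of the model's indacaterol rows.
        """
        doses = np.asarray(DoseGrid(dose_grid))
        if typical_se is None:
            if self.model is None:
                raise ValueError("typical_se must be given when the results "
                                 "are not bound to a model")
            typical_se = float(np.sqrt(np.median(self.model._ind_se2)))
        if typical_se < 0:
            raise ValueError("typical_se must be nonnegative")
        emax = self.emax_draws[:, None]
        ed50 = self.ed50_draws[:, None]
        frac = np.where(doses > 0, doses / (ed50 + doses), 0.0)
        curve = emax * frac
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2**20 + 7)))
        n = curve.shape[0]
        delta = self.samples.stacked("omega_study")[:, None] \
            * rng.standard_normal((n, doses.size))
        gamma = self.samples.stacked("omega_visit")[:, None] \
            * rng.standard_normal((n, doses.size))
        eps = typical_se * rng.standard_normal((n, doses.size))
        pred = (emax + delta + gamma) * frac + eps
        lo, hi = np.percentile(curve, [2.5, 97.5], axis=0)
        plo, phi = np.percentile(pred, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "dose_ug": doses,
            "mean": curve.mean(axis=0),
            "median": np.median(curve, axis=0),
            "ci_lo": lo, "ci_hi": hi,
            "pi_lo": plo, "pi_hi": phi,
        })

    def rank_treatments(self, dose_grid=None) -> pd.DataFrame:
        """Treatments and indacaterol doses ranked by posterior median
        response (descending).  Ties are broken by input order (stable
        sort); the ``rank`` column is 1-based."""
        dose_grid = np.asarray(dose_grid if dose_grid is not None
                               else (18.75, 37.5, 75, 150, 300, 600), float)
        entries = []
        for d in dose_grid:
            if d <= 0:
                continue
            entries.append((f"indacaterol {d:g} ug", self.effect_draws(d)))
        for label, pname in (("formoterol", "mu_for"),
                             ("salmeterol", "mu_sal"),
                             ("tiotropium", "mu_tio")):
            entries.append((label, self.samples.stacked(pname)))
        rows = []
        for label, draws in entries:
            s = _summ(draws)
            rows.append({"treatment": label, "median": s["q50"],
                         "q2.5": s["q2.5"], "q97.5": s["q97.5"]})
        df = pd.DataFrame(rows)
        df = df.sort_values("median", ascending=False, kind="stable")
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df.reset_index(drop=True)

    # -- plotting ----------------------------------------------------------
    def plot_curve(self, dose_grid=None, ax=None, **kwargs):
        """Plot the fitted curve with credible and prediction bands."""
        import matplotlib.pyplot as plt
        dose_grid = np.asarray(dose_grid if dose_grid is not None
                               else np.linspace(0, 600, 121), float)
        if dose_grid[0] > 0:
            dose_grid = np.r_[0.0, dose_grid]
        tab = self.predict_curve(dose_grid, **kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(tab["dose_ug"], tab["pi_lo"], tab["pi_hi"],
                        alpha=0.2, color="grey", label="95% prediction")
        ax.fill_between(tab["dose_ug"], tab["ci_lo"], tab["ci_hi"],
                        alpha=0.4, color="grey", label="95% credible")
        ax.plot(tab["dose_ug"], tab["mean"], color="crimson", label="mean curve")
        ax.set_xlabel("dose (μg)")
        ax.set_ylabel("trough FEV1 improvement vs placebo (mL)")
        ax.legend()
        return ax

    def plot_posteriors(self, doses=(18.75, 37.5, 75, 150, 300, 600), ax=None):
        """Kernel-density posteriors of the improvement at each dose."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde
        if ax is None:
            _, ax = plt.subplots()
        for d in doses:
            draws = self.effect_draws(d)
            grid = np.linspace(draws.min(), draws.max(), 200)
            ax.plot(grid, gaussian_kde(draws)(grid), label=f"{d:g} μg")
        ax.set_xlabel("improvement vs placebo (mL)")
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax

    def plot_ranking(self, dose_grid=None, ax=None):
        """Forest-style plot of the ranked treatments."""
        import matplotlib.pyplot as plt
        tab = self.rank_treatments(dose_grid)
        if ax is None:
            _, ax = plt.subplots()
        y = np.arange(len(tab))[::-1]
        ax.hlines(y, tab["q2.5"], tab["q97.5"], color="grey")
        ax.plot(tab["median"], y, "o", color="black")
        ax.set_yticks(y)
        ax.set_yticklabels(tab["treatment"])
        ax.set_xlabel("trough FEV1 improvement vs placebo (mL)")
        return ax
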