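"""Nonlinear mixed-effects Emax model for individual trough FEV1.

Each patient i contributes trough FEV1 measurements y_ij (mL) on study day
j (14 or 15) at an assigned once-daily dose d_i (0 = placebo).  The
structural model is

    f_ij = (E0_i + eta0_i) + (Emax_i + etam_i) * d_i / (ED50_i + d_i)

where E0_i, Emax_i, ED50_i are fixed effects possibly shifted by covariate
links (baseline FEV1 on E0 and Emax, reversibility on Emax, ED50 links
multiplicative through an exponential), and (eta0_i, etam_i) are per-patient
random effects with covariance Omega.  A transform-both-sides approach is
used: the log is applied to both observation and prediction, with additive
residual error on the log scale,

    log y_ij = log f_ij + eps_ij,   eps_ij ~ N(0, sigma^2).

Estimation uses the classical first-order (FO) method: the log-transformed
model is linearised in the random effects about zero, giving per-patient
multivariate-normal marginals with covariance G Omega G' + sigma^2 I where
G is the gradient of log f in (eta0, etam) at zero.  Patients are
independent; the marginal likelihood is maximised by quasi-Newton search on
transformed parameters (log for SDs and ED50), with a small number of
jittered multi-starts guarding against local optima.

Covariate model building follows a forward entry procedure driven by the
likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._numdiff import numerical_hessian as _numerical_hessian

__all__ = [
    "CovariateLink",
    "NlmeModelSpec",
    "validate_patient_data",
    "structural_prediction",
    "PatientLevelEmaxModel",
    "PatientLevelEmaxResults",
    "forward_select_covariates",
]

REQUIRED_COLUMNS = ("patient_id", "study_id", "day", "dose_ug",
                    "trough_fev1_ml", "baseline_fev1_ml")

#: Default centering for baseline FEV1 links (mL); the population median of
#: the modelled COPD population.
BASELINE_REF = 1300.0


@dataclass(frozen=True)
class CovariateLink:
    """One covariate effect on a structural parameter.

    parameter : 'e0', 'emax' or 'ed50'.
    covariate : column name in the patient table.
    form : 'linear' or 'power'.  Linear links enter additively as
        beta * (x - ref) on e0/emax and multiplicatively as
        exp(beta * (x - ref)) on ed50 (positivity-preserving); power links
        multiply the parameter by (x / ref) ** beta and require x > 0.
    ref : centering value; resolved to the data median (continuous) or 0
        (binary) when left None.
    beta : coefficient; serves as the starting value in fitting and as the
        true value in simulation.
    """

    parameter: str
    covariate: str
    form: str = "linear"
    ref: float | None = None
    beta: float = 0.0
    levels: tuple | None = None  # category coding frozen at model build

    def __post_init__(self):
        if self.parameter not in ("e0", "emax", "ed50"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("linear", "power"):
            raise ValueError(f"unknown link form {self.form!r}")

    @property
    def label(self) -> str:
        return f"{self.parameter}~{self.covariate}"


@dataclass(frozen=True)
class NlmeModelSpec:
    """Structural + stochastic specification of the patient-level model.

    The fixed-effect values act as starting values for estimation and as
    true values for simulation.  ``corr`` is the correlation of the two
    random effects; it is fixed unless ``estimate_corr`` is set.
    """

    e0: float = 1300.0
    emax: float = 150.0
    ed50: float = 50.0
    links: tuple = ()
    omega_e0: float = 100.0
    omega_emax: float = 50.0
    corr: float = 0.0
    sigma: float = 0.10
    estimate_corr: bool = False

    def __post_init__(self):
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if self.sigma <= 0:
            raise ValueError("residual sigma must be positive")
        if self.omega_e0 < 0 or self.omega_emax < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if not -1.0 < self.corr < 1.0:
            raise ValueError("corr must lie in (-1, 1)")

    def with_link(self, link: CovariateLink) -> "NlmeModelSpec":
        return replace(self, links=self.links + (link,))

    def omega_matrix(self) -> np.ndarray:
        off = self.corr * self.omega_e0 * self.omega_emax
        return np.array([[self.omega_e0**2, off], [off, self.omega_emax**2]])


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_patient_data(rows: pd.DataFrame):
    """Validate patient-day rows; return (validated table, rejection log).

    Row-level rules: dose nonnegative and finite, day in {14, 15}, trough
    and baseline FEV1 positive (the log transform requires positivity).
    A patient with *any* nonpositive FEV1 record is excluded entirely, and
    the exclusion is logged per dropped row.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("patient-level table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"patient-level table lacks columns {missing}")
    df = rows.copy().reset_index(drop=True)
    log = []

    def reject(mask, rule, detail):
        for idx in df.index[mask]:
            log.append({"row": int(idx), "patient_id": df.at[idx, "patient_id"],
                        "rule": rule, "detail": detail})
        return mask

    dose = pd.to_numeric(df["dose_ug"], errors="coerce")
    bad = reject(~np.isfinite(dose) | (dose < 0), "bad_dose",
                 "dose_ug must be nonnegative and finite")
    day = pd.to_numeric(df["day"], errors="coerce")
    bad |= reject(~day.isin([14, 15]) & ~bad, "bad_day",
                  "study day must be 14 or 15")
    trough = pd.to_numeric(df["trough_fev1_ml"], errors="coerce")
    base = pd.to_numeric(df["baseline_fev1_ml"], errors="coerce")
    nonpos = ~(trough > 0) | ~(base > 0)
    # exclude the whole patient when any of their records is nonpositive
    bad_pat = set(df.loc[nonpos & ~bad, "patient_id"])
    bad |= reject(df["patient_id"].isin(bad_pat) & ~bad, "nonpositive_fev1",
                  "patient excluded: nonpositive trough or baseline FEV1")
    log_df = pd.DataFrame(log, columns=["row", "patient_id", "rule", "detail"])
    valid = df.loc[~bad].reset_index(drop=True)
    if len(valid) == 0:
        raise ValueError("every patient-level row was rejected:\n"
                         + log_df.to_string(index=False))
    for c in ("dose_ug", "trough_fev1_ml", "baseline_fev1_ml", "day"):
        valid[c] = pd.to_numeric(valid[c])
    if len(bad_pat):
        warnings.warn(f"excluded {len(bad_pat)} patient(s) with nonpositive "
                      "FEV1 records", UserWarning)
    return valid, log_df


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------

def _encode_covariate(values: pd.Series, levels: tuple | None = None) -> np.ndarray:
    """Numeric pass-through; binary categoricals coded 0/1 by level order.

    ``levels`` pins the coding learned at model build so that prediction
    frames use the same mapping as the training data.
    """
    if levels is None and pd.api.types.is_numeric_dtype(values):
        return values.to_numpy(float)
    if levels is None:
        levels = tuple(sorted(values.dropna().unique()))
    if len(levels) > 2:
        raise ValueError(
            f"covariate {values.name!r} has {len(levels)} levels; only "
            "binary categorical covariates are supported")
    mapping = {lev: float(k) for k, lev in enumerate(levels)}
    out = values.map(mapping) if not pd.api.types.is_numeric_dtype(values) \
        else values.astype(float)
    arr = np.asarray(out, float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"covariate {values.name!r} has values outside the "
                         f"model's levels {levels}")
    return arr


def _resolve_links(links, data: pd.DataFrame):
    """Fill in missing centering values (data median / 0) and freeze the
    categorical coding observed in the data."""
    resolved = []
    for link in links:
        if link.covariate not in data.columns:
            raise ValueError(f"covariate column {link.covariate!r} missing")
        numeric = pd.api.types.is_numeric_dtype(data[link.covariate])
        levels = link.levels
        if levels is None and not numeric:
            levels = tuple(sorted(data[link.covariate].dropna().unique()))
        x = _encode_covariate(data[link.covariate], levels)
        ref = link.ref
        if ref is None:
            ref = float(np.median(x)) if numeric else 0.0
        resolved.append(replace(link, ref=ref, levels=levels))
    return tuple(resolved)


def _apply_links(spec: NlmeModelSpec, data: pd.DataFrame):
    """Per-row structural parameters (e0_i, emax_i, ed50_i) after links."""
    n = len(data)
    e0 = np.full(n, spec.e0)
    emax = np.full(n, spec.emax)
    log_ed50 = np.full(n, np.log(spec.ed50))
    for link in spec.links:
        if link.ref is None:
            raise ValueError(
                f"link {link.label} has unresolved centering; build the "
                "model (or pass ref=) first")
        x = _encode_covariate(data[link.covariate], link.levels)
        if link.form == "linear":
            if link.parameter == "e0":
                e0 = e0 + link.beta * (x - link.ref)
            elif link.parameter == "emax":
                emax = emax + link.beta * (x - link.ref)
            else:
                log_ed50 = log_ed50 + link.beta * (x - link.ref)
        else:  # power
            if np.any(x <= 0) or link.ref <= 0:
                raise ValueError(f"power link {link.label} needs positive "
                                 "covariate and reference")
            factor = link.beta * np.log(x / link.ref)
            if link.parameter == "e0":
                e0 = e0 * np.exp(factor)
            elif link.parameter == "emax":
                emax = emax * np.exp(factor)
            else:
                log_ed50 = log_ed50 + factor
    return e0, emax, np.exp(log_ed50)


def structural_prediction(spec: NlmeModelSpec, randoms, record) -> float | np.ndarray:
    """Trough FEV1 (mL) predicted by the structural model.

    ``randoms`` is the pair (eta_e0, eta_emax); ``record`` is a mapping /
    Series with dose_ug and any covariates the spec's links require (or a
    DataFrame for a vectorised call).  A nonpositive prediction is flagged
    with a warning because the log transform is undefined there.
    """
    df = record if isinstance(record, pd.DataFrame) \
        else pd.DataFrame([dict(record)])
    eta0, etam = randoms
    e0, emax, ed50 = _apply_links(spec, df)
    d = df["dose_ug"].to_numpy(float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    pred = (e0 + eta0) + (emax + etam) * d / (ed50 + d)
    if np.any(pred <= 0):
        warnings.warn("structural prediction is nonpositive; the log "
                      "transform is undefined there", UserWarning)
    return pred if isinstance(record, pd.DataFrame) else float(pred[0])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class PatientLevelEmaxModel:
    """Patient-level Emax NLME model bound to a validated dataset.

    ``PatientLevelEmaxModel(data, spec).fit()`` maximises the first-order
    marginal likelihood and returns :class:`PatientLevelEmaxResults`.
    """

    def __init__(self, data: pd.DataFrame, spec: NlmeModelSpec | None = None):
        self.data, self.rejection_log = validate_patient_data(data)
        spec = spec or NlmeModelSpec()
        self.spec = replace(spec, links=_resolve_links(spec.links, self.data))
        self._prepare()

    @classmethod
    def from_csv(cls, path, spec: NlmeModelSpec | None = None):
        return cls(pd.read_csv(path), spec=spec)

    def _prepare(self):
        # sort rows so each patient's records are contiguous (likelihood is
        # invariant to the original ordering)
        codes, _ = pd.factorize(self.data["patient_id"])
        order = np.argsort(codes, kind="stable")
        self._df = self.data.iloc[order].reset_index(drop=True)
        codes = codes[order]
        starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
        sizes = np.diff(np.r_[starts, len(codes)])
        self._z = np.log(self._df["trough_fev1_ml"].to_numpy(float))
        self._dose = self._df["dose_ug"].to_numpy(float)
        self._block_starts = starts
        self._block_sizes = sizes
        self._idx1 = starts[sizes == 1]
        s2 = starts[sizes == 2]
        self._idx2a, self._idx2b = s2, s2 + 1
        self._big_blocks = [(s, s + n) for s, n in zip(starts, sizes) if n > 2]
        self._patient_first = starts  # one row per patient for id lookup

    # -- FO marginal likelihood -------------------------------------------
    def fo_loglike(self, spec: NlmeModelSpec) -> float:
        """First-order marginal log-likelihood of log trough FEV1.

        Linearises log f in the random effects about zero: patient blocks
        are multivariate normal with mean log f(theta, 0, x) and covariance
        G Omega G' + sigma^2 I, G = d log f / d eta at 0.  Returns -inf for
        parameter values giving nonpositive predictions (log undefined).
        """
        e0, emax, ed50 = _apply_links(spec, self._df)
        d = self._dose
        fr = d / (ed50 + d)
        f0 = e0 + emax * fr
        if np.any(f0 <= 0) or not np.all(np.isfinite(f0)):
            return -np.inf
        m = np.log(f0)
        g0 = 1.0 / f0
        g1 = fr / f0
        r = self._z - m
        O = spec.omega_matrix()
        s2 = spec.sigma**2
        # per-row marginal variances q_i' Omega q_i
        v = (O[0, 0] * g0 * g0 + 2 * O[0, 1] * g0 * g1 + O[1, 1] * g1 * g1)
        ll = 0.0
        i1 = self._idx1
        if i1.size:
            vv = v[i1] + s2
            if np.any(vv <= 0):
                bad = self._df["patient_id"].iloc[i1[np.argmax(vv <= 0)]]
                raise ValueError(f"singular covariance for patient {bad!r}")
            ll += float(np.sum(-0.5 * (np.log(2 * np.pi * vv)
                                       + r[i1] ** 2 / vv)))
        a, b = self._idx2a, self._idx2b
        if a.size:
            v11 = v[a] + s2
            v22 = v[b] + s2
            v12 = (O[0, 0] * g0[a] * g0[b] + O[1, 1] * g1[a] * g1[b]
                   + O[0, 1] * (g0[a] * g1[b] + g1[a] * g0[b]))
            # cancellation-free determinant: v[a]*v[b] - v12^2 is a PSD Gram
            # determinant (exactly >= 0), so the clamp only removes rounding
            # noise and det stays positive whenever sigma > 0
            gram = np.maximum(v[a] * v[b] - v12**2, 0.0)
            det = gram + s2 * (v[a] + v[b]) + s2 * s2
            if np.any(det <= 0):
                bad = self._df["patient_id"].iloc[a[np.argmax(det <= 0)]]
                raise ValueError(f"singular covariance for patient {bad!r}")
            quad = (v22 * r[a] ** 2 - 2 * v12 * r[a] * r[b]
                    + v11 * r[b] ** 2) / det
            ll += float(np.sum(-0.5 * (2 * np.log(2 * np.pi)
                                       + np.log(det) + quad)))
        for lo, hi in self._big_blocks:
            Q = np.column_stack([g0[lo:hi], g1[lo:hi]])
            V = Q @ O @ Q.T + s2 * np.eye(hi - lo)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                bad = self._df["patient_id"].iloc[lo]
                raise ValueError(f"singular covariance for patient {bad!r}")
            x = np.linalg.solve(L, r[lo:hi])
            ll += float(-0.5 * ((hi - lo) * np.log(2 * np.pi)
                                + 2 * np.sum(np.log(np.diag(L)))
                                + x @ x))
        return ll

    # -- parameter vector mapping -----------------------------------------
    def _theta_names(self, spec: NlmeModelSpec):
        names = ["e0", "emax", "log_ed50", "log_omega_e0", "log_omega_emax"]
        if spec.estimate_corr:
            names.append("atanh_corr")
        names.append("log_sigma")
        names += [f"beta[{link.label}]" for link in spec.links]
        return names

    def _spec_to_theta(self, spec: NlmeModelSpec) -> np.ndarray:
        th = [spec.e0, spec.emax, np.log(spec.ed50),
              np.log(max(spec.omega_e0, 1e-6)),
              np.log(max(spec.omega_emax, 1e-6))]
        if spec.estimate_corr:
            th.append(np.arctanh(np.clip(spec.corr, -0.99, 0.99)))
        th.append(np.log(spec.sigma))
        th += [link.beta for link in spec.links]
        return np.array(th, float)

    def _theta_to_spec(self, theta: np.ndarray, spec: NlmeModelSpec) -> NlmeModelSpec:
        i = 5
        corr = spec.corr
        if spec.estimate_corr:
            corr = float(np.tanh(theta[5]))
            i = 6
        sigma = float(np.exp(theta[i]))
        betas = theta[i + 1:]
        links = tuple(replace(link, beta=float(b))
                      for link, b in zip(spec.links, betas))
        return replace(spec, e0=float(theta[0]), emax=float(theta[1]),
                       ed50=float(np.exp(theta[2])),
                       omega_e0=float(np.exp(theta[3])),
                       omega_emax=float(np.exp(theta[4])),
                       corr=corr, sigma=sigma, links=links)

    def _theta_scale(self, spec: NlmeModelSpec) -> np.ndarray:
        """Per-parameter scale factors so the optimizer works on O(1)
        quantities (effects are O(100) mL; a covariate slope's natural
        scale is the effect scale divided by the covariate spread)."""
        scales = [100.0, 100.0, 1.0, 1.0, 1.0]
        if spec.estimate_corr:
            scales.append(1.0)
        scales.append(1.0)
        for link in spec.links:
            x = _encode_covariate(self._df[link.covariate], link.levels)
            spread = max(float(np.std(x)), 1e-12)
            if link.form == "power":
                scales.append(1.0)
            elif link.parameter == "ed50":
                scales.append(1.0 / spread)
            else:
                scales.append(100.0 / spread)
        return np.array(scales)

    def _nll(self, theta: np.ndarray, spec: NlmeModelSpec) -> float:
        try:
            s = self._theta_to_spec(theta, spec)
        except (ValueError, OverflowError):
            return np.inf
        ll = self.fo_loglike(s)
        return -ll if np.isfinite(ll) else np.inf

    # -- fitting -----------------------------------------------------------
    def fit(self, start: NlmeModelSpec | None = None, n_starts: int = 3,
            jitter_seed: int = 0, maxiter: int = 500,
            compute_se: bool = True) -> "PatientLevelEmaxResults":
        """Maximise the FO marginal likelihood.

        ``n_starts`` quasi-Newton runs are launched: the first from the
        spec's own values, the rest from deterministically jittered copies
        (fixed ``jitter_seed``), and the best optimum is kept.  Standard
        errors come from the numerically differentiated curvature of -2LL
        at the optimum.  Non-convergence yields a flagged fit with a
        warning, not an exception.
        """
        spec = self.spec if start is None else \
            replace(start, links=_resolve_links(start.links, self._df))
        theta0 = self._spec_to_theta(spec)
        if not np.isfinite(self._nll(theta0, spec)):
            raise ValueError("likelihood is not finite at the start values")
        scale = self._theta_scale(spec)
        obj = lambda phi: self._nll(phi * scale, spec)
        phi0 = theta0 / scale
        rng = np.random.default_rng(jitter_seed)
        best = None
        for k in range(max(1, n_starts)):
            ph = phi0 if k == 0 else \
                phi0 + 0.1 * rng.standard_normal(phi0.size) \
                * np.maximum(np.abs(phi0), 0.5)
            if not np.isfinite(obj(ph)):
                continue
            res = optimize.minimize(
                obj, ph, method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 20 * maxiter,
                         "ftol": 1e-12, "gtol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success)
        if not converged:
            warnings.warn("FO optimisation did not report convergence: "
                          f"{best.message}", RuntimeWarning)
        theta_hat = best.x * scale
        fitted_spec = self._theta_to_spec(theta_hat, spec)
        names = self._theta_names(spec)
        cov = None
        if compute_se:
            H = _numerical_hessian(obj, best.x, rel_step=1e-4)
            cov_phi = _safe_inverse(H)
            if cov_phi is not None:
                cov = cov_phi * np.outer(scale, scale)
        return PatientLevelEmaxResults(
            model=self, spec=fitted_spec, theta=theta_hat,
            theta_names=names, minus2ll=2.0 * best.fun,
            cov_theta=cov, converged=converged)


def _safe_inverse(H):
    try:
        # curvature of -2LL; parameter covariance is 2 * H^{-1}... the
        # Hessian here is of -LL, so cov = H^{-1}
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            return None
        return cov
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class PatientLevelEmaxResults:
    """Fitted patient-level model: estimates, uncertainty, predictions.

    ``params`` maps natural-scale parameter names to estimates; ``bse`` and
    ``conf_int()`` are delta-method SEs / Wald 95% CIs (log-scale intervals
    back-transformed for positive parameters).  ``minus2ll`` is -2 times the
    maximised FO marginal log-likelihood.
    """

    _NATURAL = {"log_ed50": "ed50", "log_omega_e0": "omega_e0",
                "log_omega_emax": "omega_emax", "log_sigma": "sigma",
                "atanh_corr": "corr"}

    def __init__(self, model, spec, theta, theta_names, minus2ll,
                 cov_theta, converged):
        self.model = model
        self.spec = spec
        self.theta = np.asarray(theta)
        self.theta_names = list(theta_names)
        self.minus2ll = float(minus2ll)
        self.cov_theta = cov_theta
        self.converged = converged

    @property
    def llf(self) -> float:
        return -0.5 * self.minus2ll

    def _rows(self):
        se_theta = (np.sqrt(np.diag(self.cov_theta))
                    if self.cov_theta is not None
                    else np.full(self.theta.size, np.nan))
        z = stats.norm.ppf(0.975)
        for name, th, se in zip(self.theta_names, self.theta, se_theta):
            if name.startswith("log_"):
                est = np.exp(th)
                yield (self._NATURAL[name], est, est * se,
                       np.exp(th - z * se), np.exp(th + z * se))
            elif name == "atanh_corr":
                est = np.tanh(th)
                yield ("corr", est, (1 - est**2) * se,
                       np.tanh(th - z * se), np.tanh(th + z * se))
            else:
                label = name[5:-1] if name.startswith("beta[") else name
                yield (label, th, se, th - z * se, th + z * se)

    @property
    def params(self) -> pd.Series:
        return pd.Series({r[0]: r[1] for r in self._rows()})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({r[0]: r[2] for r in self._rows()})

    def conf_int(self) -> pd.DataFrame:
        rows = {r[0]: (r[3], r[4]) for r in self._rows()}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def summary(self) -> pd.DataFrame:
        """Parameter table: estimate, SE, Wald 95% CI, plus fit metadata."""
        tab = pd.DataFrame(
            [(r[0], r[1], r[2], r[3], r[4]) for r in self._rows()],
            columns=["parameter", "estimate", "se", "ci_lo", "ci_hi"],
        ).set_index("parameter")
        tab.attrs["minus2ll"] = self.minus2ll
        tab.attrs["converged"] = self.converged
        tab.attrs["n_patients"] = len(self.model._block_starts)
        tab.attrs["n_records"] = len(self.model._df)
        return tab

    # -- predictions -------------------------------------------------------
    def _typical_row(self, dose, **covariates) -> pd.DataFrame:
        doses = np.atleast_1d(np.asarray(dose, float))
        base = {}
        for link in self.spec.links:
            base.setdefault(link.covariate, link.ref)
        base.update(covariates)
        rows = pd.DataFrame({"dose_ug": doses})
        for k, v in base.items():
            rows[k] = v
        return rows

    def predict_improvement(self, baseline_fev1: float, dose_grid) -> pd.DataFrame:
        """Typical-patient improvement over placebo (mL) per dose.

        Structural prediction at zero random effects for the requested
        baseline FEV1 (other covariates at their reference values), minus
        the dose-0 prediction at the same covariates.  Warns when the
        baseline lies beyond twice the observed range.
        """
        if baseline_fev1 <= 0:
            raise ValueError("baseline must be positive")
        obs = self.model._df["baseline_fev1_ml"]
        if not (obs.min() / 2 <= baseline_fev1 <= obs.max() * 2):
            warnings.warn("baseline FEV1 far outside the modelled range; "
                          "prediction is an extrapolation", UserWarning)
        doses = np.asarray(dose_grid, float)
        rows = self._typical_row(np.r_[0.0, doses],
                                 baseline_fev1_ml=baseline_fev1)
        pred = structural_prediction(self.spec, (0.0, 0.0), rows)
        return pd.DataFrame({"dose_ug": doses,
                             "improvement_ml": pred[1:] - pred[0]})

    def relative_improvement(self, baseline_fev1: float, dose_grid) -> pd.DataFrame:
        """Improvement as a percentage of the baseline FEV1, per dose."""
        tab = self.predict_improvement(baseline_fev1, dose_grid)
        tab["improvement_pct_baseline"] = (100.0 * tab["improvement_ml"]
                                           / baseline_fev1)
        return tab

    def predict_by_severity(self, group: str, dose_grid,
                            severity_column: str = "severity") -> pd.DataFrame:
        """Population-average improvement for a GOLD severity group.

        Averages the typical-patient improvement over the empirical
        covariate rows (one per patient) of the requested group.
        """
        df = self.model._df.iloc[self.model._patient_first]
        if severity_column not in df.columns:
            raise ValueError(f"column {severity_column!r} not in the data")
        members = df[df[severity_column].astype(str).str.lower()
                     .str.startswith(str(group).lower()[:3])]
        if len(members) == 0:
            raise ValueError(f"no patients in severity group {group!r}")
        doses = np.asarray(dose_grid, float)
        total = np.zeros(doses.size)
        covs = {link.covariate for link in self.spec.links}
        for _, patient in members.iterrows():
            rows = self._typical_row(np.r_[0.0, doses])
            for c in covs:
                if c in patient.index:
                    rows[c] = patient[c]
            pred = structural_prediction(self.spec, (0.0, 0.0), rows)
            total += pred[1:] - pred[0]
        return pd.DataFrame({"dose_ug": doses,
                             "improvement_ml": total / len(members)})

    def plot_improvement(self, baselines=(800, 1300, 1800), dose_grid=None, ax=None):
        """Improvement-vs-dose curves for several baseline FEV1 values."""
        import matplotlib.pyplot as plt
        doses = np.asarray(dose_grid if dose_grid is not None
                           else np.linspace(0, 600, 121))
        if ax is None:
            _, ax = plt.subplots()
        for b in baselines:
            tab = self.predict_improvement(b, doses)
            ax.plot(tab["dose_ug"], tab["improvement_ml"],
                    label=f"baseline {b:g} mL")
        ax.set_xlabel("dose (μg)")
        ax.set_ylabel("trough FEV1 improvement vs placebo (mL)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# covariate forward selection
# ---------------------------------------------------------------------------

def forward_select_covariates(data: pd.DataFrame, base_spec: NlmeModelSpec,
                              candidates, alpha: float = 0.01,
                              **fit_kwargs):
    """Forward covariate entry by likelihood-ratio test.

    At each round every remaining candidate link is added to the current
    model and refitted; the candidate with the smallest LRT p-value below
    ``alpha`` (chi-square, df = 1 added parameter) enters.  Selection stops
    when no candidate qualifies.  A candidate whose fit fails is skipped
    with a trace entry.  Returns ``(final_results, trace)`` where the trace
    records every tested model's -2LL, the LRT statistic and p-value, and
    whether it was selected — reproducible bit-for-bit given data, spec and
    fit settings.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    current_spec = base_spec
    current = PatientLevelEmaxModel(data, current_spec).fit(
        compute_se=False, **fit_kwargs)
    remaining = list(candidates)
    trace = []
    step = 0
    while remaining:
        step += 1
        tested = []
        for cand in remaining:
            row = {"step": step, "candidate": cand.label,
                   "base_minus2ll": current.minus2ll}
            try:
                fit = PatientLevelEmaxModel(
                    data, current.spec.with_link(replace(cand, beta=0.0))
                ).fit(compute_se=False, **fit_kwargs)
                lrt = max(current.minus2ll - fit.minus2ll, 0.0)
                row.update(minus2ll=fit.minus2ll, lrt=lrt,
                           p_value=float(stats.chi2.sf(lrt, df=1)),
                           status="ok")
                tested.append((row["p_value"], cand, fit))
            except Exception as exc:  # candidate fit failure: skip, log
                row.update(minus2ll=np.nan, lrt=np.nan, p_value=np.nan,
                           status=f"failed: {exc}")
            row["selected"] = False
            trace.append(row)
        qualifying = [t for t in tested if t[0] < alpha]
        if not qualifying:
            break
        qualifying.sort(key=lambda t: t[0])
        p, chosen, fit = qualifying[0]
        for row in trace:
            if row["step"] == step and row["candidate"] == chosen.label \
                    and row["status"] == "ok":
                row["selected"] = True
        current = fit
        remaining = [c for c in remaining if c.label != chosen.label]
    # refit the winner with standard errors
    final = PatientLevelEmaxModel(data, current.spec).fit(**fit_kwargs)
    return final, pd.DataFrame(trace)
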