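"""Synthetic study-level and patient-level datasets.

These generators emulate the statistical structure the two analyses assume,
so the whole pipeline — meta-analysis, NLME fitting, covariate selection and
dose selection — is testable without trial data.  The study-level generator
reproduces an 11-study development programme (arm sizes and treatment
allocation patterned on the published programme; 2-week crossovers up to a
52-week parallel-group study) with between-study and between-visit
variability on Emax calibrated so that roughly 95% of simulated study-visit
LSM contrasts fall within +/-60 mL of the mean curve.  The patient-level
generator draws a COPD population whose baseline FEV1 is log-normal with
median 1300 mL and about 25% of patients below 1 L (range truncated to the
observed 500-3200 mL), assigns seven once-daily dose arms including placebo,
and produces trough FEV1 through the same structural model the NLME stage
fits (additive per-patient random effects on E0 and Emax; log-scale residual).

Both generators are deterministic given their seed and emit tables in the
exact delimited format the fitting modules read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .patient import CovariateLink, NlmeModelSpec, structural_prediction

__all__ = [
    "StudyLevelTruth",
    "PatientLevelTruth",
    "default_study_design",
    "generate_study_level",
    "generate_patient_level",
]


# ---------------------------------------------------------------------------
# study level
# ---------------------------------------------------------------------------

# (study, treatment, dose, n) per arm; visits assigned by study duration.
_DESIGN_ARMS = [
    # study, duration_weeks, [(treatment, dose, n), ...]
    ("S01", 2,  [("indacaterol", 300, 144), ("salmeterol", 0, 72)]),
    ("S02", 52, [("indacaterol", 300, 437), ("indacaterol", 600, 428),
                 ("formoterol", 0, 435)]),
    ("S03", 26, [("indacaterol", 75, 130), ("indacaterol", 150, 420),
                 ("indacaterol", 300, 418), ("indacaterol", 600, 123),
                 ("formoterol", 0, 123), ("tiotropium", 0, 420)]),
    ("S04", 2,  [("indacaterol", 300, 66), ("salmeterol", 0, 65)]),
    ("S05", 12, [("indacaterol", 150, 211)]),
    ("S06", 12, [("indacaterol", 150, 114), ("indacaterol", 300, 116)]),
    ("S07", 26, [("indacaterol", 150, 188), ("indacaterol", 300, 188)]),
    ("S08", 26, [("indacaterol", 150, 333), ("salmeterol", 0, 334)]),
    ("S09", 12, [("indacaterol", 75, 163)]),
    ("S10", 12, [("indacaterol", 75, 159)]),
    ("S11", 12, [("indacaterol", 18.75, 92), ("indacaterol", 37.5, 91),
                 ("indacaterol", 75, 94), ("indacaterol", 150, 92),
                 ("salmeterol", 0, 92)]),
]

_VISITS_BY_DURATION = {
    2: ("Week 2",),
    12: ("Week 2", "Week 8", "Week 12"),
    26: ("Week 2", "Week 8", "Week 12", "Month 6"),
    52: ("Week 2", "Week 12", "Month 3", "Month 6"),
}


def default_study_design() -> pd.DataFrame:
    """Arm x visit design table of the 11-study programme.

    Columns: study_id, treatment, dose_ug, visit_id, n.  Steady-state
    visits run from Week 2 to at most Month 6 regardless of study length.
    """
    rows = []
    for study, duration, arms in _DESIGN_ARMS:
        for visit in _VISITS_BY_DURATION[duration]:
            for treatment, dose, n in arms:
                rows.append({"study_id": study, "treatment": treatment,
                             "dose_ug": float(dose), "visit_id": visit,
                             "n": int(n)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StudyLevelTruth:
    """True parameter values and design for the study-level generator.

    ``arm_sd`` is the per-patient residual SD (mL) from which each arm's
    contrast SE is computed as ``arm_sd * sqrt(2 / n)``.  The default
    variability calibration (omega_study 25 mL, omega_visit 15 mL,
    arm_sd 250 mL) reproduces a ~50 mL visit-to-visit spread of LSMs and a
    +/-60 mL 95% prediction band at the plateau.
    """

    emax: float = 177.0
    ed50: float = 28.0
    omega_study: float = 25.0
    omega_visit: float = 15.0
    omega_sal_visit: float = 15.0
    mu_for: float = 110.0
    mu_sal: float = 100.0
    mu_tio: float = 130.0
    arm_sd: float = 250.0
    design: pd.DataFrame = field(default_factory=default_study_design)

    def __post_init__(self):
        for name in ("omega_study", "omega_visit", "omega_sal_visit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if len(self.design) == 0:
            raise ValueError("design must be nonempty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("design")
        return d


def generate_study_level(truth: StudyLevelTruth | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate one study-level LSM dataset from ``truth``.

    Draws one delta per study, one gamma per indacaterol arm-visit, one
    gamma_S per salmeterol arm-visit, then each LSM contrast from
    N(arm mean, se^2) with se = arm_sd * sqrt(2/n).  Byte-identical output
    for a given seed.
    """
    truth = truth or StudyLevelTruth()
    rng = np.random.default_rng(seed)
    design = truth.design.reset_index(drop=True)
    studies = list(dict.fromkeys(design["study_id"]))
    delta = {s: rng.normal(0.0, truth.omega_study) for s in studies}

    rows = []
    for _, arm in design.iterrows():
        trt = arm["treatment"]
        se = truth.arm_sd * np.sqrt(2.0 / arm["n"])
        if trt == "indacaterol":
            frac = arm["dose_ug"] / (truth.ed50 + arm["dose_ug"])
            gamma = rng.normal(0.0, truth.omega_visit)
            mean = (truth.emax + delta[arm["study_id"]] + gamma) * frac
        elif trt == "salmeterol":
            mean = truth.mu_sal + rng.normal(0.0, truth.omega_sal_visit)
        elif trt == "formoterol":
            mean = truth.mu_for
        elif trt == "tiotropium":
            mean = truth.mu_tio
        else:
            raise ValueError(f"unknown treatment {trt!r} in design")
        rows.append({
            "study_id": arm["study_id"], "treatment": trt,
            "dose_ug": arm["dose_ug"] if trt == "indacaterol" else np.nan,
            "visit_id": arm["visit_id"],
            "lsm_contrast_ml": rng.normal(mean, se),
            "se_ml": se, "n": int(arm["n"]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient level
# ---------------------------------------------------------------------------

def _default_patient_spec() -> NlmeModelSpec:
    # reference patient: baseline FEV1 1300 mL, reversibility 12%
    return NlmeModelSpec(
        e0=1300.0, emax=185.0, ed50=19.0,
        links=(
            CovariateLink("e0", "baseline_fev1_ml", "linear",
                          ref=1300.0, beta=0.95),
            CovariateLink("emax", "baseline_fev1_ml", "linear",
                          ref=1300.0, beta=0.12),
            CovariateLink("ed50", "baseline_fev1_ml", "linear",
                          ref=1300.0, beta=-5e-4),
            CovariateLink("emax", "reversibility_pct", "linear",
                          ref=12.0, beta=1.5),
        ),
        omega_e0=120.0, omega_emax=50.0, corr=0.0, sigma=0.12,
    )


@dataclass(frozen=True)
class PatientLevelTruth:
    """True parameter values and population for the patient-level generator.

    ``spec`` carries the structural truth (reference fixed effects at
    baseline 1300 mL / reversibility 12%, covariate link coefficients,
    random-effect SDs, log-scale residual SD).  Baseline FEV1 is log-normal
    with the given median and log-SD (default 0.389, placing ~25% of
    patients below 1 L), truncated by rejection to ``baseline_range``
    (the observed 0.5-3.2 L span).  Patients are allocated to ``doses``
    round-robin and each contributes one record per entry of ``days``.
    """

    spec: NlmeModelSpec = field(default_factory=_default_patient_spec)
    n_patients: int = 1835
    doses: tuple = (0.0, 18.75, 37.5, 75.0, 150.0, 300.0, 600.0)
    days: tuple = (14, 15)
    baseline_median: float = 1300.0
    baseline_log_sd: float = 0.389
    baseline_range: tuple = (500.0, 3200.0)
    reversibility_mean: float = 12.0
    reversibility_sd: float = 8.0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.doses or any(d < 0 for d in self.doses):
            raise ValueError("doses must be nonnegative")
        if not set(self.days) <= {14, 15}:
            raise ValueError("days must be a subset of {14, 15}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"]["links"] = [asdict(l) for l in self.spec.links]
        return d


def generate_patient_level(truth: PatientLevelTruth | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate one patient-level trough-FEV1 dataset from ``truth``.

    Covariates are sampled first (baseline FEV1, reversibility, GOLD
    severity derived from baseline < 1 L, independent binary demographics),
    then per-patient random effects (eta_E0, eta_Emax), then the structural
    prediction; a log-scale residual is added and back-transformed.  Raises
    if any structural prediction (random effects included, residual noise
    not yet added) is nonpositive — such a truth cannot feed the
    log-transformed model.  Byte-identical output for a given seed.
    """
    truth = truth or PatientLevelTruth()
    rng = np.random.default_rng(seed)
    n = truth.n_patients

    lo, hi = truth.baseline_range
    mu = np.log(truth.baseline_median)
    baseline = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(mu, truth.baseline_log_sd, size=2 * (n - filled)))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        baseline[filled:filled + draw.size] = draw
        filled += draw.size

    reversibility = np.clip(
        rng.normal(truth.reversibility_mean, truth.reversibility_sd, n),
        -10.0, 60.0)
    severity = np.where(baseline < 1000.0, "severe", "moderate")
    ics_use = rng.choice(["no", "yes"], n, p=[0.4, 0.6])
    smoker = rng.choice(["current", "ex"], n, p=[0.4, 0.6])
    sex = rng.choice(["female", "male"], n, p=[0.3, 0.7])
    age_group = rng.choice(["<65", ">=65"], n, p=[0.55, 0.45])

    dose = np.asarray(truth.doses, float)[np.arange(n) % len(truth.doses)]
    study = np.where(np.arange(n) % 2 == 0, "DR1", "DR2")

    eta = rng.multivariate_normal([0.0, 0.0], truth.spec.omega_matrix(), n)

    frames = []
    for day in truth.days:
        frames.append(pd.DataFrame({
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "study_id": study, "day": day, "dose_ug": dose,
            "baseline_fev1_ml": baseline,
            "reversibility_pct": reversibility,
            "severity": severity, "ics_use": ics_use, "smoker": smoker,
            "sex": sex, "age_group": age_group,
        }))
    df = pd.concat(frames, ignore_index=True)
    eta_rows = np.tile(eta, (len(truth.days), 1))
    pred = structural_prediction(truth.spec, (eta_rows[:, 0], eta_rows[:, 1]), df)
    if np.any(pred <= 0):
        raise ValueError(
            "truth produces nonpositive structural predictions; the "
            "log-transformed observation model is undefined")
    df.insert(4, "trough_fev1_ml",
              np.exp(np.log(pred) + truth.spec.sigma
                     * rng.standard_normal(len(df))))
    return df.sort_values(["patient_id", "day"]).reset_index(drop=True)
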