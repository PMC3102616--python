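"""Dose-selection decision rules over a fitted dose-response.

Three rules drive dose selection against the minimal clinically important
difference (MCID) of 120 mL in trough FEV1 vs placebo (the midpoint of the
100-140 mL range):

- **minimum effective dose (MED)** — the lowest tested dose whose median
  predicted improvement reaches the MCID;
- **optimal dose** — the lowest dose meeting the MED criterion whose median
  improvement also exceeds every active comparator's median;
- **maximum dose** — the lowest dose whose 95% interval for the predicted
  response brackets the predicted maximum response (the Emax median),
  i.e. the dose at which the response is indistinguishable from the plateau.

All rules operate on per-dose posterior medians and interval bounds, so
they apply equally to the study-level posterior and to bootstrap or Wald
summaries of the patient-level fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DoseDecision",
    "minimum_effective_dose",
    "optimal_dose",
    "maximum_dose",
    "decide_doses",
]

MCID_ML = 120.0


def _sorted(doses, *arrays):
    doses = np.asarray(doses, float)
    order = np.argsort(doses)
    return (doses[order],) + tuple(np.asarray(a, float)[order] for a in arrays)


def minimum_effective_dose(doses, median_effects, mcid: float = MCID_ML,
                           strict: bool = False):
    """Lowest dose whose median effect reaches the MCID, or None.

    ``strict`` switches the comparison from >= (default, per the
    '>= 120 mL vs placebo' reading) to >.
    """
    doses, med = _sorted(doses, median_effects)
    ok = med > mcid if strict else med >= mcid
    idx = np.flatnonzero(ok)
    return float(doses[idx[0]]) if idx.size else None


def optimal_dose(doses, median_effects, comparator_medians=None,
                 mcid: float = MCID_ML, strict: bool = False):
    """Lowest MED-qualifying dose superior to all active comparators.

    ``comparator_medians`` is a mapping label -> median effect (mL);
    superiority is a point comparison of posterior medians.  With no
    comparators the rule reduces to the MED.  Returns None when no dose
    qualifies.
    """
    doses, med = _sorted(doses, median_effects)
    ok = med > mcid if strict else med >= mcid
    if comparator_medians:
        best = max(comparator_medians.values())
        ok &= med > best
    idx = np.flatnonzero(ok)
    return float(doses[idx[0]]) if idx.size else None


def maximum_dose(doses, ci_lo, ci_hi, emax_median):
    """Lowest dose whose 95% interval brackets the predicted maximum.

    The predicted maximum response is the posterior median of Emax; a dose
    qualifies when ci_lo <= emax_median <= ci_hi.  Returns None when no
    dose's interval reaches the plateau.
    """
    doses, lo, hi = _sorted(doses, ci_lo, ci_hi)
    ok = (lo <= emax_median) & (emax_median <= hi)
    idx = np.flatnonzero(ok)
    return float(doses[idx[0]]) if idx.size else None


@dataclass(frozen=True)
class DoseDecision:
    """Outcome of the three decision rules with per-dose evidence."""

    med: float | None
    optimal: float | None
    maximum: float | None
    evidence: pd.DataFrame
    mcid: float = MCID_ML

    def __post_init__(self):
        defined = [d for d in (self.med, self.optimal, self.maximum)
                   if d is not None]
        if defined != sorted(defined):
            raise ValueError(
                f"inconsistent decision: med={self.med}, "
                f"optimal={self.optimal}, maximum={self.maximum}")

    def report(self) -> str:
        """One-page plain-text decision report."""
        fmt = lambda d: f"{d:g} ug" if d is not None else "not attained"
        lines = [
            "Dose-selection decision (MCID = %.0f mL vs placebo)" % self.mcid,
            "=" * 52,
            f"minimum effective dose : {fmt(self.med)}",
            f"optimal dose           : {fmt(self.optimal)}",
            f"maximum dose           : {fmt(self.maximum)}",
            "",
            "Per-dose evidence:",
            self.evidence.to_string(index=False, float_format="%.1f"),
        ]
        return "\n".join(lines)


def decide_doses(results, dose_grid=None, mcid: float = MCID_ML,
                 comparators: bool = True,
                 prob_cutoff: float | None = None) -> DoseDecision:
    """Apply all three rules to a study-level posterior.

    ``results`` is a :class:`~emaxdr.study.StudyLevelEmaxResults`.  With
    ``prob_cutoff`` set (e.g. 0.5), comparator superiority is judged by the
    posterior probability P(dose effect > comparator effect) > cutoff for
    every comparator instead of the default point comparison of medians.
    """
    doses = np.sort(np.asarray(
        dose_grid if dose_grid is not None
        else (18.75, 37.5, 75, 150, 300, 600), float))
    doses = doses[doses > 0]
    med_eff, lo, hi, p_mcid = [], [], [], []
    for d in doses:
        draws = results.effect_draws(d)
        q = np.percentile(draws, [2.5, 50, 97.5])
        lo.append(q[0]); med_eff.append(q[1]); hi.append(q[2])
        p_mcid.append(float(np.mean(draws > mcid)))
    comp = {}
    if comparators:
        for label, pname in (("formoterol", "mu_for"),
                             ("salmeterol", "mu_sal"),
                             ("tiotropium", "mu_tio")):
            comp[label] = float(np.median(results.samples.stacked(pname)))
    emax_median = float(np.median(results.emax_draws))

    med = minimum_effective_dose(doses, med_eff, mcid)
    if prob_cutoff is None or not comp:
        opt = optimal_dose(doses, med_eff, comp or None, mcid)
    else:
        opt = None
        for d, m in zip(doses, med_eff):
            if m < mcid:
                continue
            draws = results.effect_draws(d)
            wins = all(
                np.mean(draws > results.samples.stacked(pn)) > prob_cutoff
                for pn in ("mu_for", "mu_sal", "mu_tio"))
            if wins:
                opt = float(d)
                break
    mx = maximum_dose(doses, lo, hi, emax_median)

    evidence = pd.DataFrame({
        "dose_ug": doses, "median_ml": med_eff,
        "q2.5_ml": lo, "q97.5_ml": hi,
        "p_exceeds_mcid": p_mcid,
    })
    for label, value in comp.items():
        evidence[f"{label}_median_ml"] = value
    return DoseDecision(med=med, optimal=opt, maximum=mx,
                        evidence=evidence, mcid=mcid)
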