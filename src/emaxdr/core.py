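"""Hyperbolic Emax dose-response algebra.

The Emax model is the standard pharmacodynamic description of a saturating
dose-response relationship,

    E(d) = Emax * d / (ED50 + d),

where ``Emax`` is the asymptotic maximal (placebo-corrected) effect and
``ED50`` the dose producing half of it.  Throughout this package effects are
in mL of trough FEV1 and doses in micrograms; there is no unit-conversion
layer.

These functions are pure and array-aware: ``dose`` may be a scalar or a numpy
array and the result follows numpy broadcasting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmaxParams",
    "DoseGrid",
    "emax_effect",
    "fraction_of_max",
    "dose_for_fraction",
    "dose_for_effect",
]


@dataclass(frozen=True)
class EmaxParams:
    """Parameters of the hyperbolic Emax model.

    Parameters
    ----------
    emax : float
        Maximal placebo-corrected effect (mL).  May carry any sign in
        fitting intermediates; fitted bronchodilator models have emax > 0.
    ed50 : float
        Dose producing half the maximal effect (μg); must be positive.
    """

    emax: float
    ed50: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.emax):
            raise ValueError(f"emax must be finite, got {self.emax}")
        if not (np.isfinite(self.ed50) and self.ed50 > 0):
            raise ValueError(f"ed50 must be positive and finite, got {self.ed50}")


@dataclass(frozen=True)
class DoseGrid:
    """A strictly increasing grid of nonnegative doses (μg).

    The first element may be 0 (placebo).
    """

    doses: tuple

    def __init__(self, doses) -> None:
        arr = np.asarray(doses, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("dose grid must be a nonempty 1-d sequence")
        if arr[0] < 0:
            raise ValueError("doses must be nonnegative")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("doses must be strictly increasing")
        object.__setattr__(self, "doses", tuple(arr.tolist()))

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.doses, dtype=dtype)

    def __iter__(self):
        return iter(self.doses)

    def __len__(self) -> int:
        return len(self.doses)


#: The six once-daily doses evaluated in the development programme (μg).
TESTED_DOSES = DoseGrid((18.75, 37.5, 75.0, 150.0, 300.0, 600.0))


def _check_dose(dose) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("dose must be nonnegative and finite")
    return d


def emax_effect(dose, params: EmaxParams):
    """Placebo-corrected effect at ``dose`` under the Emax model.

    Returns ``emax * dose / (ed50 + dose)`` (mL): 0 at dose 0, strictly
    increasing and concave in dose for emax > 0, with asymptote ``emax``.
    """
    d = _check_dose(dose)
    out = params.emax * d / (params.ed50 + d)
    return out if out.ndim else float(out)


def fraction_of_max(dose, ed50):
    """Fraction of the maximal effect attained at ``dose``: d / (ed50 + d).

    Lies in [0, 1); equals 0.5 exactly at dose = ed50.  This is how the
    "percentage of maximum effect" rows of a dose-ranging summary table are
    derived from an ED50 estimate.
    """
    d = _check_dose(dose)
    if not (np.isfinite(ed50) and ed50 > 0):
        raise ValueError(f"ed50 must be positive, got {ed50}")
    out = d / (ed50 + d)
    return out if out.ndim else float(out)


def dose_for_fraction(p, ed50):
    """Dose attaining fraction ``p`` of the maximal effect (inverse of
    :func:`fraction_of_max`): ed50 * p / (1 - p).

    ``p`` must lie strictly inside (0, 1); e.g. p = 0.9 gives the ED90,
    which is 9 * ED50 by this algebra.
    """
    parr = np.asarray(p, dtype=float)
    if np.any(parr <= 0) or np.any(parr >= 1):
        raise ValueError("fraction must lie strictly in (0, 1)")
    if not (np.isfinite(ed50) and ed50 > 0):
        raise ValueError(f"ed50 must be positive, got {ed50}")
    out = ed50 * parr / (1.0 - parr)
    return out if out.ndim else float(out)


def dose_for_effect(target, params: EmaxParams):
    """Smallest dose achieving effect ``target`` mL, or None if unattainable.

    For 0 < target < emax returns ed50 * target / (emax - target); a target
    at or above the asymptote is unattainable (None); a nonpositive target
    needs no drug (0.0).  Requires emax > 0.
    """
    if params.emax <= 0:
        raise ValueError("dose_for_effect requires emax > 0")
    if target <= 0:
        return 0.0
    if target >= params.emax:
        return None
    return params.ed50 * target / (params.emax - target)
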