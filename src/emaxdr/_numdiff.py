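"""Finite-difference derivatives of scalar objectives."""

from __future__ import annotations

import numpy as np

__all__ = ["numerical_hessian"]


def numerical_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian of ``fun`` at ``x`` (O(n^2) evaluations)."""
    x = np.asarray(x, float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H
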