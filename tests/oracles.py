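"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own evaluation paths: the
Mittag-Leffler oracle sums the defining power series in adaptive arbitrary
precision (mpmath), and the classical PECE oracle is a direct transcription
of the order-1 predictor-corrector recurrence.
"""

from __future__ import annotations

import math

import mpmath as mp
import numpy as np


def ml_oracle(alpha: float, beta: float, z: float) -> float:
    """E_{alpha,beta}(z) by arbitrary-precision series summation.

    Working precision is chosen from the largest series term (the
    cancellation for negative z is ~exp(|z|^(1/alpha))); raises if the
    required precision is impractical (use a closed form instead there).
    """
    digits = abs(z) ** (1.0 / alpha) * 0.4343 if z < 0 else 0.0
    dps = 40 + int(digits)
    if dps > 350:
        raise ValueError("cancellation too severe for the series oracle")
    with mp.workdps(dps):
        s = mp.mpf(0)
        n = 0
        while True:
            term = mp.mpf(z) ** n / mp.gamma(mp.mpf(alpha) * n + beta)
            s += term
            if n > 3 and abs(term) < mp.mpf(10) ** (-dps + 5) * max(1, abs(s)):
                break
            n += 1
        return float(s)


def classical_pece(rhs, y0: np.ndarray, t0: float, t1: float, h: float) -> np.ndarray:
    """Classical Adams-Bashforth-Moulton PECE in its full-memory quadrature
    form: rectangle-rule predictor and composite-trapezoid corrector over the
    whole rhs history,

        y^P_{n+1} = y_0 + h * sum_{j<=n} f_j
        y_{n+1}   = y_0 + h/2 * (f(t_{n+1}, y^P) + f_0 + 2 sum_{1<=j<=n} f_j),

    which is exactly what the fractional scheme's weights collapse to at
    order 1.  Sums are recomputed naively each step (no shared machinery).
    Returns the state matrix on the uniform grid."""
    n_steps = int(round((t1 - t0) / h))
    t = t0 + h * np.arange(n_steps + 1)
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    y = np.empty((n_steps + 1, len(y0)))
    y[0] = y0
    f_hist = [np.asarray(rhs(t[0], y[0]), dtype=float)]
    for n in range(n_steps):
        pred = y0 + h * sum(f_hist)
        fp = np.asarray(rhs(t[n + 1], pred), dtype=float)
        inner = sum(f_hist[1:]) if n >= 1 else 0.0
        y[n + 1] = y0 + 0.5 * h * (fp + f_hist[0] + 2.0 * inner)
        f_hist.append(np.asarray(rhs(t[n + 1], y[n + 1]), dtype=float))
    return y


def erfc_closed_form(x: float) -> float:
    """E_{1/2}(-x) = exp(x^2) erfc(x), in arbitrary precision."""
    with mp.workdps(40):
        return float(mp.exp(x**2) * mp.erfc(x))
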