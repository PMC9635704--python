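"""Perturbed tumor growth models with distributed drug-response delay.

Three formulations of the same delayed-response idea are provided:

* **Erlang TCM** — the classical transit compartment chain.  Damaged cells
  pass through n first-order stages with rate k1 (stage residence time is
  Erlang(n, k1) distributed; mean residence time n/k1):

      u'   = k_in(u, w) - k_out(C, u)
      y1'  = k_out(C, u) - k1 y1
      yi'  = k1 (y_{i-1} - y_i),   i = 2..n,     w = u + y1 + ... + yn

* **Fractional TCM** — the compartment chain is replaced by a single damaged
  pool whose elimination is delayed through a Mittag-Leffler residence
  distribution, which leads to a Caputo fractional derivative of order
  1 - alpha in the elimination term:

      u' = k_in(u, w) - k_out(C, u)
      y' = k_out(C, u) - tau^{-alpha} D^{1-alpha} y,        w = u + y

  For simulation the mixed equation is rewritten with the latent state
  z = D^{1-alpha} y (z(0) = 0, forced by y(0) = 0) using the semigroup
  property of the Caputo derivative, giving the multi-order system

      u' = k_in - eta C u            (order 1)
      D^alpha z = eta C u - tau^{-alpha} z     (order alpha)
      y' = eta C u - tau^{-alpha} z            (order 1)

  i.e. y is integrated as an order-1 state driven by the same right-hand
  side as D^alpha z.

* **Convolution form** — the master equation both models derive from,

      u' = k_in - k_out,   y' = k_out - (k_out * f)(t),

  for an arbitrary residence density f (Erlang, Mittag-Leffler, or a point
  delay, in which case the convolution collapses to the lagged term
  k_out(t - T) and the system is a DDE).  This is the validation surface: the
  chain and multi-order forms must reproduce it.

Growth and kill follow Simeoni et al.: k_in switches smoothly from
exponential growth (rate lambda0) below the threshold mass w_th = lambda1 /
lambda0 to linear growth (rate lambda1) above it, with sharpness phi; the
kill flux is k_out = eta * C * u.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .errors import ConfigurationError
from .fde_solver import MultiOrderSystem, SolverConfig, Trajectory, solve_multiorder
from .mittag_leffler import MLDelayParameters, ml_survival

__all__ = [
    "GrowthParameters",
    "ErlangTCMParameters",
    "FractionalTCMParameters",
    "k_in",
    "k_out",
    "build_erlang_system",
    "build_fractional_system",
    "simulate_erlang",
    "simulate_fractional",
    "simulate_convolution_tcm",
    "ErlangDensity",
    "MittagLefflerDensity",
    "PointDelay",
    "REFERENCE_GROWTH_PARAMETERS",
    "CONCENTRATION_UNIT",
    "scaled_concentration",
]

#: Concentration unit (ng/ml) in which the potency eta is expressed.
#:
#: The PK module reports plasma concentration in ng/ml (peak ~4.4e4 for the
#: reference regimen), but the reference potencies (eta ~ 0.25-0.38) are only
#: dynamically consistent — kill rate eta*C of order 1/day, tumor regrowth
#: once dosing stops — when C enters the PD terms in units of 1e4 ng/ml
#: (10 ug/ml).  eta therefore carries ml/(1e4 ng)/day, and every reference
#: simulation couples the models to C(t)/CONCENTRATION_UNIT.  See the methods
#: note for the unit analysis.
CONCENTRATION_UNIT = 1.0e4


def scaled_concentration(C: "Callable", unit: float = CONCENTRATION_UNIT):
    """Wrap a ng/ml concentration function into the PD unit (C/unit)."""

    def scaled(t):
        return C(t) / unit

    return scaled


@dataclass(frozen=True)
class GrowthParameters:
    """Simeoni growth parameters.

    lambda0 : first-order (exponential-phase) growth rate, day^-1.
    lambda1 : linear-phase growth rate, g/day.
    phi : switching sharpness (dimensionless); values below 10 blur the
        exponential-to-linear transition, so a warning is emitted.
    w0 : initial tumor mass, g.
    """

    lambda0: float = 0.25
    lambda1: float = 0.4603
    phi: float = 20.0
    w0: float = 0.0121

    def __post_init__(self):
        if min(self.lambda0, self.lambda1, self.phi, self.w0) <= 0:
            raise ValueError("all growth parameters must be positive")
        if self.phi < 10:
            warnings.warn(
                f"phi={self.phi} < 10: the exponential/linear growth switch "
                "is no longer sharp", stacklevel=2)

    @property
    def threshold(self) -> float:
        """Mass w_th = lambda1/lambda0 at which growth switches regimes."""
        return self.lambda1 / self.lambda0


@dataclass(frozen=True)
class ErlangTCMParameters:
    growth: GrowthParameters
    eta: float  # drug potency, ml/(ng*day)
    k1: float   # transit rate, day^-1
    n: int      # number of transit compartments

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n must be a positive integer")


@dataclass(frozen=True)
class FractionalTCMParameters:
    growth: GrowthParameters
    eta: float  # drug potency, ml/(ng*day)
    delay: MLDelayParameters

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


def k_in(u, w, g: GrowthParameters):
    """Simeoni perturbed growth flux lambda0*u*[1+(lambda0 w/lambda1)^phi]^(-1/phi).

    Exponential growth (~lambda0*u) for w well below the threshold
    lambda1/lambda0, linear growth (~lambda1*u/w) well above it.  Evaluated in
    the log domain so the switch term cannot overflow at large phi.  Accepts
    scalars or arrays; masses must be nonnegative.
    """
    u_arr = np.asarray(u, dtype=float)
    w_arr = np.asarray(w, dtype=float)
    if np.any(u_arr < 0) or np.any(w_arr < 0):
        raise ValueError("masses must be nonnegative")
    with np.errstate(divide="ignore"):
        L = g.phi * np.log(np.maximum(w_arr, 0.0) * g.lambda0 / g.lambda1)
    # (1 + e^L)^(1/phi) computed as exp(logaddexp(0, L)/phi)
    denom_log = np.logaddexp(0.0, L) / g.phi
    out = g.lambda0 * u_arr * np.exp(-denom_log)
    return float(out) if np.ndim(u) == 0 and np.ndim(w) == 0 else out


def k_out(C, u, eta: float):
    """First-order kill flux eta * C * u (g/day)."""
    C_arr = np.asarray(C, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if np.any(C_arr < 0) or np.any(u_arr < 0) or eta < 0:
        raise ValueError("concentration, mass and potency must be nonnegative")
    out = eta * C_arr * u_arr
    return float(out) if np.ndim(C) == 0 and np.ndim(u) == 0 else out


# ---------------------------------------------------------------------------
# system builders

def build_erlang_system(
    p: ErlangTCMParameters, C: Callable[[float], float]
) -> MultiOrderSystem:
    """Classical ODE system (u, y1..yn) for the Erlang transit chain.

    All orders are 1, so the shared multi-order solver reduces to classical
    trapezoidal PECE on the same grid as the fractional model — convenient for
    side-by-side comparison.  Initial state (w0, 0, ..., 0).
    """
    g = p.growth
    n = p.n

    def rhs(t, y):
        u = y[0]
        w = y.sum()
        dy = np.empty(n + 1)
        kill = p.eta * C(t) * max(u, 0.0)
        dy[0] = k_in(max(u, 0.0), max(w, 0.0), g) - kill
        dy[1] = kill - p.k1 * y[1]
        for i in range(2, n + 1):
            dy[i] = p.k1 * (y[i - 1] - y[i])
        return dy

    return MultiOrderSystem(
        orders=np.ones(n + 1),
        rhs=rhs,
        initial_state=np.array([g.w0] + [0.0] * n),
        state_names=["u"] + [f"y{i}" for i in range(1, n + 1)],
    )


def build_fractional_system(
    p: FractionalTCMParameters, C: Callable[[float], float]
) -> MultiOrderSystem:
    """Multi-order system (u, z, y) with Caputo orders (1, alpha, 1).

    z = D^{1-alpha} y is the latent delay state from the semigroup rewrite;
    the total observable tumor mass is w = u + y (z is not part of w).
    """
    g = p.growth
    alpha = p.delay.alpha
    tau_a = p.delay.tau ** (-alpha)
    eta = p.eta

    def rhs(t, y):
        u, z, yd = y
        w = max(u, 0.0) + max(yd, 0.0)
        kill = eta * C(t) * max(u, 0.0)
        elim = kill - tau_a * z
        return np.array([k_in(max(u, 0.0), w, g) - kill, elim, elim])

    return MultiOrderSystem(
        orders=np.array([1.0, alpha, 1.0]),
        rhs=rhs,
        initial_state=np.array([g.w0, 0.0, 0.0]),
        state_names=["u", "z", "y"],
    )


def _grid_cached(C: Callable, cfg: SolverConfig) -> Callable[[float], float]:
    """Precompute C on the solver grid; the ABM scheme only queries grid nodes."""
    t = cfg.t_start + cfg.step * np.arange(cfg.n_steps + 1)
    vals = np.asarray(C(t), dtype=float)
    t0, h, n_max = cfg.t_start, cfg.step, cfg.n_steps

    def cached(tq: float) -> float:
        i = int(round((tq - t0) / h))
        if 0 <= i <= n_max and abs(t0 + i * h - tq) < 1e-9:
            return float(vals[i])
        return float(C(tq))

    return cached


def simulate_erlang(
    p: ErlangTCMParameters, C: Callable[[float], float], cfg: SolverConfig
) -> Trajectory:
    """Solve the Erlang TCM on the uniform grid; w = u + sum(y_i)."""
    return solve_multiorder(build_erlang_system(p, _grid_cached(C, cfg)), cfg)


def simulate_fractional(
    p: FractionalTCMParameters, C: Callable[[float], float], cfg: SolverConfig
) -> Trajectory:
    """Solve the fractional TCM (semigroup multi-order form); w = u + y."""
    return solve_multiorder(build_fractional_system(p, _grid_cached(C, cfg)), cfg)


def total_mass(traj: Trajectory) -> np.ndarray:
    """Observable tumor mass w(t) for either model's trajectory.

    Erlang: u + y1 + ... + yn.  Fractional: u + y (the latent z is excluded).
    """
    names = list(traj.state_names)
    cols = [i for i, nm in enumerate(names) if nm == "u" or nm.startswith("y")]
    if "z" in names:
        cols = [names.index("u"), names.index("y")]
    return traj.states[:, cols].sum(axis=1)


# ---------------------------------------------------------------------------
# delay densities for the convolution oracle

@dataclass(frozen=True)
class ErlangDensity:
    """Erlang(n, k1) stage-residence density."""

    n: int
    k1: float

    def survival(self, t):
        return _gamma_dist.sf(np.asarray(t, dtype=float), self.n, scale=1.0 / self.k1)


@dataclass(frozen=True)
class MittagLefflerDensity:
    """Mittag-Leffler residence density with survival E_alpha(-(t/tau)^alpha)."""

    params: MLDelayParameters

    def survival(self, t):
        return ml_survival(t, self.params)


@dataclass(frozen=True)
class PointDelay:
    """Dirac point delay: every damaged cell resides exactly T days (DDE)."""

    T: float

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("delay T must be nonnegative")


def simulate_convolution_tcm(
    growth: GrowthParameters,
    eta: float,
    density,
    C: Callable[[float], float],
    cfg: SolverConfig,
) -> Trajectory:
    """Integrate the master convolution equation directly (validation oracle).

        u' = k_in - k_out,   y' = k_out - (k_out * f)(t)

    The convolution over the stored k_out history uses product-trapezoidal
    quadrature with *exact* density mass per subinterval, m_j = S(t_j) -
    S(t_{j+1}), which handles the t^{alpha-1} singularity of the ML density at
    the origin analytically.  For a :class:`PointDelay` the convolution
    collapses to the lagged term k_out(t - T) (zero for t < T), evaluated by
    linear interpolation on the grid.

    Time stepping is Heun predictor-corrector on the same uniform grid as the
    other formulations.  Returns a trajectory with states (u, y).
    """
    N = cfg.n_steps
    h = cfg.step
    t = cfg.t_start + h * np.arange(N + 1)

    point = isinstance(density, PointDelay)
    if not point:
        S = np.asarray(density.survival(t - cfg.t_start), dtype=float)
        if abs(S[0] - 1.0) > 1e-8:
            raise ConfigurationError(
                f"density survival S(0)={S[0]!r} != 1: not a normalized density")
        masses = S[:-1] - S[1:]  # exact density mass on each subinterval
        if np.any(masses < -1e-12):
            raise ConfigurationError("density survival is not nonincreasing")

    ko = np.zeros(N + 1)  # k_out history at grid nodes
    C_grid = np.asarray(C(t), dtype=float)

    states = np.empty((N + 1, 2))
    states[0] = (growth.w0, 0.0)
    ko[0] = eta * C_grid[0] * growth.w0

    def conv_at(n: int, ko_hist: np.ndarray) -> float:
        """(k_out * f)(t_n) from node values ko_hist[0..n]."""
        if point:
            x = t[n] - density.T
            if x < t[0]:
                return 0.0
            return float(np.interp(x, t[: n + 1], ko_hist[: n + 1]))
        if n == 0:
            return 0.0
        kavg = 0.5 * (ko_hist[:n] + ko_hist[1: n + 1])
        # sum_j m_j * avg(k(t_n - t_j), k(t_n - t_{j+1}))
        return float(np.dot(masses[:n][::-1], kavg))

    def deriv(u, y, kill, conv):
        return (
            k_in(max(u, 0.0), max(u, 0.0) + max(y, 0.0), growth) - kill,
            kill - conv,
        )

    for n in range(N):
        u, y = states[n]
        conv_n = conv_at(n, ko)
        du, dy = deriv(u, y, ko[n], conv_n)

        # predictor (forward Euler)
        up, yp = u + h * du, y + h * dy
        ko[n + 1] = eta * C_grid[n + 1] * max(up, 0.0)
        conv_p = conv_at(n + 1, ko)
        dup, dyp = deriv(up, yp, ko[n + 1], conv_p)

        # corrector (trapezoid)
        un1 = u + 0.5 * h * (du + dup)
        yn1 = y + 0.5 * h * (dy + dyp)
        if not (math.isfinite(un1) and math.isfinite(yn1)):
            raise ConfigurationError(
                f"convolution integration diverged at t={t[n+1]:.6g}")
        states[n + 1] = (un1, yn1)
        ko[n + 1] = eta * C_grid[n + 1] * max(un1, 0.0)

    return Trajectory(t=t, states=states, state_names=["u", "y"])


REFERENCE_GROWTH_PARAMETERS = GrowthParameters()
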