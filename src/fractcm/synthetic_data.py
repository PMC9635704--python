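"""Synthetic tumor datasets emulating the mouse-150 study design.

The reference dataset (ten tumor-mass observations from one xenograft mouse)
is not publicly tabulated, so every workflow in this package is exercised on
synthetic data generated from either TCM with known ground-truth parameters:
implant at day 0 with w0 = 0.0121 g, ten daily boluses of 4.5e7 ng/kg starting
day 13, ten observation times spanning days 0-60 (pre-treatment, treatment,
and regrowth phases), with optional multiplicative lognormal observation
noise.  Multiplicative noise is the natural choice here: tumor masses span
~3 orders of magnitude over the study and fits are judged on a log scale.

The default observation times are a package convention (the real ones are not
published); they are config-overridable and stamped into the dataset metadata
together with the generating parameters and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import GenerationFailureError
from .estimation import TumorDataset
from .fde_solver import SolverConfig
from .pk import DoseSchedule, PKParameters, solve_pk
from .tumor_models import (
    ErlangTCMParameters,
    FractionalTCMParameters,
    scaled_concentration,
    simulate_erlang,
    simulate_fractional,
    total_mass,
)

__all__ = ["StudyDesign", "default_observation_times", "generate_dataset",
           "apply_lognormal_noise"]


@dataclass(frozen=True)
class StudyDesign:
    """Mouse-150-like study design.

    w0 : initial tumor mass (g) at implant (day 0).
    dose_start_day, n_doses, dose_amount : daily bolus regimen (ng/kg).
    observation_times : 10 sampling days in [0, 60]; None -> package default.
    noise_sigma : std dev of log-observation noise; 0 = noise-free.
    """

    w0: float = 0.0121
    implant_day: float = 0.0
    dose_start_day: float = 13.0
    n_doses: int = 10
    dose_amount: float = 4.5e7
    observation_times: tuple = None
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.observation_times is not None:
            ts = tuple(float(t) for t in self.observation_times)
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("observation times must be strictly increasing")
            object.__setattr__(self, "observation_times", ts)

    @property
    def dose_schedule(self) -> DoseSchedule:
        return DoseSchedule.daily(self.n_doses, self.dose_amount,
                                  self.dose_start_day)


def default_observation_times(design: StudyDesign | None = None) -> np.ndarray:
    """Ten strictly increasing sampling days covering the three study phases.

    Two pre-treatment points (before day 13), four during/just after the
    ten-day dosing window, and four in the regrowth phase (after day 23), all
    within [0, 60].  Pure function of the design (the default ignores it).
    """
    if design is not None and design.observation_times is not None:
        return np.asarray(design.observation_times, dtype=float)
    return np.array([0.0, 7.0, 13.0, 16.0, 19.0, 22.0, 26.0, 33.0, 45.0, 60.0])


def apply_lognormal_noise(masses: np.ndarray, sigma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal observation noise: w * exp(sigma * N(0,1))."""
    masses = np.asarray(masses, dtype=float)
    if sigma == 0:
        return masses.copy()
    return masses * np.exp(sigma * rng.standard_normal(masses.shape))


def generate_dataset(
    truth: ErlangTCMParameters | FractionalTCMParameters,
    design: StudyDesign | None = None,
    pk: PKParameters | None = None,
    seed: int = 0,
    cfg: SolverConfig | None = None,
) -> TumorDataset:
    """Simulate total tumor mass at the design's observation times.

    Returns a :class:`TumorDataset` whose metadata embeds the ground-truth
    parameters, design, and seed; deterministic under ``seed``.  Raises
    :class:`GenerationFailureError` if the underlying simulation fails.
    """
    design = design or StudyDesign()
    pk = pk or PKParameters()
    obs = default_observation_times(design)
    if cfg is None:
        cfg = SolverConfig(t_start=0.0, t_end=float(obs[-1]))
    if obs[0] < cfg.t_start or obs[-1] > cfg.t_end + 1e-9:
        raise ValueError("observation times must lie inside the simulation window")

    C = scaled_concentration(solve_pk(pk, design.dose_schedule))
    try:
        if isinstance(truth, ErlangTCMParameters):
            traj = simulate_erlang(truth, C, cfg)
            model = "erlang"
        else:
            traj = simulate_fractional(truth, C, cfg)
            model = "fractional"
    except Exception as exc:
        raise GenerationFailureError(f"simulation failed: {exc}") from exc

    w = total_mass(traj)
    idx = np.clip(np.round((obs - cfg.t_start) / cfg.step).astype(int),
                  0, len(w) - 1)
    w_obs = w[idx]

    rng = np.random.default_rng(seed)
    observed = apply_lognormal_noise(w_obs, design.noise_sigma, rng)

    truth_params = asdict(truth)  # recursive: nested parameter blocks -> dicts
    return TumorDataset(
        times=obs,
        masses=observed,
        meta={
            "synthetic": True,
            "model": model,
            "truth": truth_params,
            "seed": int(seed),
            "noise_sigma": float(design.noise_sigma),
            "design": {k: v for k, v in asdict(design).items()},
            "step": cfg.step,
        },
    )
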