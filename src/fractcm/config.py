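"""Run configuration: a single structured (YAML) file with reference defaults.

Experiments carry many parameters whose defaults are the reference study
values (growth lambda0=0.25, lambda1=0.4603, phi=20, w0=0.0121; PK k01=1.6,
k21=0.2353, k12=0.1699, V=1028; ten daily boluses of 4.5e7 from day 13;
solver step 2^-8), so the interface is one human-editable config file; CLI
flags override individual entries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .fde_solver import SolverConfig
from .mittag_leffler import MLDelayParameters
from .pk import DoseSchedule, PKParameters
from .tumor_models import (
    ErlangTCMParameters,
    FractionalTCMParameters,
    GrowthParameters,
)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Flat experiment configuration with reference defaults."""

    model: str = "fractional"            # erlang | fractional
    experiment: str = "simulate"
    seed: int = 0
    output_dir: str = "results"
    dataset: str | None = None           # input dataset file for fit/compare

    # growth
    lambda0: float = 0.25
    lambda1: float = 0.4603
    phi: float = 20.0
    w0: float = 0.0121
    # Erlang TCM
    n: int = 4
    k1: float = 0.54379
    eta_erlang: float = 0.37847
    # fractional TCM
    alpha: float = 0.945
    tau: float = 3.6852
    eta_fractional: float = 0.24657
    # PK + dosing
    k01: float = 1.6
    k21: float = 0.2353
    k12: float = 0.1699
    V: float = 1028.0
    dose_amount: float = 4.5e7
    n_doses: int = 10
    dose_start_day: float = 13.0
    dose_file: str | None = None
    # solver
    t_start: float = 0.0
    t_end: float = 60.0
    step: float = 2.0**-8
    # experiment-specific knobs
    subset_sizes: tuple = (2, 3, 4, 5, 6, 8)
    n_candidates: tuple = (1, 2, 3, 4, 5, 6)
    n_samples: int = 200
    noise_sigma: float = 0.0
    # sensitivity sampling distributions (uniform ranges; tau is lognormal
    # in the log-mean/log-variance parameterization)
    alpha_lo: float = 0.5
    alpha_hi: float = 0.95
    eta_lo: float = 0.05
    eta_hi: float = 0.5
    tau_log_mean: float = 1.3042705256412999  # log(3.685)
    tau_log_var: float = 0.5

    # ------------------------------------------------------------------
    def growth(self) -> GrowthParameters:
        return GrowthParameters(self.lambda0, self.lambda1, self.phi, self.w0)

    def pk(self) -> PKParameters:
        return PKParameters(self.k01, self.k21, self.k12, self.V)

    def doses(self) -> DoseSchedule:
        if self.dose_file:
            return DoseSchedule.from_file(self.dose_file)
        return DoseSchedule.daily(self.n_doses, self.dose_amount,
                                  self.dose_start_day)

    def solver(self) -> SolverConfig:
        return SolverConfig(self.t_start, self.t_end, self.step)

    def sensitivity_distributions(self):
        from .sensitivity import ParameterDistribution

        return (
            ParameterDistribution("alpha", "uniform", (self.alpha_lo, self.alpha_hi)),
            ParameterDistribution("tau", "lognormal",
                                  (self.tau_log_mean, self.tau_log_var)),
            ParameterDistribution("eta", "uniform", (self.eta_lo, self.eta_hi)),
        )

    def erlang_params(self) -> ErlangTCMParameters:
        return ErlangTCMParameters(growth=self.growth(), eta=self.eta_erlang,
                                   k1=self.k1, n=self.n)

    def fractional_params(self) -> FractionalTCMParameters:
        return FractionalTCMParameters(
            growth=self.growth(), eta=self.eta_fractional,
            delay=MLDelayParameters(self.alpha, self.tau))

    def model_params(self):
        return (self.erlang_params() if self.model == "erlang"
                else self.fractional_params())

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (flat key/value, optional nesting ignored at one
    level) and apply keyword overrides; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping: {path}")
        for key, val in raw.items():
            if isinstance(val, dict):  # allow one level of grouping
                data.update(val)
            else:
                data[key] = val
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for tup_key in ("subset_sizes", "n_candidates"):
        if tup_key in data:
            data[tup_key] = tuple(data[tup_key])
    # coerce numerics: YAML 1.1 reads "4.5e7" (no sign) as a string
    for key, val in data.items():
        default = RunConfig.__dataclass_fields__[key].default
        if isinstance(default, float) and isinstance(val, (str, int)):
            data[key] = float(val)
        elif isinstance(default, int) and not isinstance(default, bool) \
                and isinstance(val, str):
            data[key] = int(val)
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid configuration: {exc}") from exc
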