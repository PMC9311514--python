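"""Synthetic forcing and growth observations emulating the pond experiment.

The emulated design: post-larvae of 1.02 cm total length stocked into an
integrated aquaculture pond in early summer, grown for 180 days under a
seasonal temperature cycle with daily variability, sampled every 15 days
(~30 individuals per sampling, lengths and weights recorded as mean ± SD),
fed at an effectively constant scaled functional response (default 0.62).
The true pond temperature series is unpublished; the sinusoid + noise
defaults here are a labelled stand-in with a realistic subtropical range.

Individual measurement scatter is multiplicative lognormal (sizes are
positive and spread grows with the mean), mean-preserving at the requested
coefficient of variation.  A single integer seed drives separate,
reproducible streams for the temperature noise and the observation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DEBParams, ForcingSeries, InvalidInput, OrganismState, structure_from_length
from .estimation import DataBundle, ZeroVariateEntry, _predict_zero_variate
from .simulator import SimConfig, integrate

__all__ = [
    "GrowthObservations",
    "ScenarioSpec",
    "gen_temperature",
    "gen_growth_observations",
    "gen_zero_variate_bundle",
]


@dataclass
class GrowthObservations:
    """Sampling table: day, mean length (cm), mean wet weight (g), SDs, n."""

    day: np.ndarray
    length_cm: np.ndarray
    weight_g: np.ndarray
    sd_length: np.ndarray | None = None
    sd_weight: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.length_cm = np.asarray(self.length_cm, dtype=float)
        self.weight_g = np.asarray(self.weight_g, dtype=float)
        if self.day.ndim != 1:
            raise InvalidInput("observations must be 1-D")
        if self.length_cm.shape != self.day.shape or self.weight_g.shape != self.day.shape:
            raise InvalidInput("length and weight columns must match day")
        if np.any(np.diff(self.day) <= 0):
            raise InvalidInput("days must be strictly increasing")
        if np.any(self.length_cm <= 0) or np.any(self.weight_g <= 0):
            raise InvalidInput("mean lengths and weights must be positive")
        for name in ("sd_length", "sd_weight", "n"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float)
                if col.shape != self.day.shape:
                    raise InvalidInput(f"{name} column must match day")
                if np.any(col < 0):
                    raise InvalidInput(f"{name} must be nonnegative")
                setattr(self, name, col)
        if self.n is not None and np.any(self.n < 1):
            raise InvalidInput("n must be >= 1")

    def __len__(self) -> int:
        return self.day.size

    def to_dataframe(self):
        import pandas as pd

        data = {"day": self.day, "length_cm": self.length_cm,
                "weight_g": self.weight_g}
        if self.sd_length is not None:
            data["sd_length"] = self.sd_length
        if self.sd_weight is not None:
            data["sd_weight"] = self.sd_weight
        if self.n is not None:
            data["n"] = self.n.astype(int)
        return pd.DataFrame(data)


@dataclass
class ScenarioSpec:
    """Pond-experiment scenario; defaults are the emulated study conditions."""

    duration_d: float = 180.0
    sampling_interval_d: float = 15.0
    initial_length_cm: float = 1.02
    initial_weight_g: float = 8.7e-3
    true_f: float = 0.62
    temp_mean_C: float = 24.0
    temp_amplitude_C: float = 6.0
    temp_phase_d: float = 16.0      # sinusoid peaks ~day 75 (mid-summer for a June start)
    temp_noise_sd_C: float = 0.8
    obs_cv: float = 0.05
    n_per_sampling: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_d <= self.sampling_interval_d:
            raise InvalidInput("duration must exceed the sampling interval")
        if not 0.0 <= self.true_f <= 1.0:
            raise InvalidInput("true_f must lie in [0, 1]")
        if self.obs_cv < 0:
            raise InvalidInput("obs_cv must be nonnegative")
        if self.n_per_sampling < 1:
            raise InvalidInput("n_per_sampling must be >= 1")

    def replace(self, **changes) -> "ScenarioSpec":
        return replace(self, **changes)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def gen_temperature(spec: ScenarioSpec) -> ForcingSeries:
    """Daily seasonal temperature series (sinusoid + seeded Gaussian noise)."""
    days = np.arange(0.0, spec.duration_d + 0.5, 1.0)
    temp_c = (spec.temp_mean_C
              + spec.temp_amplitude_C
              * np.sin(2.0 * math.pi * (days + spec.temp_phase_d) / 365.0))
    if spec.temp_noise_sd_C > 0:
        temp_c = temp_c + _rng(spec.seed, 0).normal(0.0, spec.temp_noise_sd_C,
                                                    size=days.size)
    return ForcingSeries(days, temp_c + 273.15, f=spec.true_f)


def true_trajectory(spec: ScenarioSpec, params: DEBParams,
                    config: SimConfig | None = None):
    """Noiseless growth trajectory of the scenario (also used by the generator)."""
    forcing = gen_temperature(spec)
    v0 = structure_from_length(spec.initial_length_cm, params)
    state = OrganismState(E=spec.true_f * params.EM * v0, V=v0,
                          EH=params.EHj, sex="female")
    cfg = config or SimConfig()
    cfg = SimConfig(t0=0.0, t_end=spec.duration_d, dt=cfg.dt,
                    integrator=cfg.integrator, starvation=cfg.starvation,
                    acceleration=cfg.acceleration, aging=cfg.aging)
    return integrate(state, forcing, params, cfg), forcing


def gen_growth_observations(spec: ScenarioSpec, params: DEBParams,
                            config: SimConfig | None = None) -> GrowthObservations:
    """Noisy sampling table from the scenario's true trajectory.

    At each sampling day the individual lengths and weights of
    ``n_per_sampling`` animals are drawn as mean-preserving multiplicative
    lognormal perturbations of the trajectory value at the stated CV; the
    table reports their mean and SD.  With CV = 0 the means equal the
    trajectory exactly and the SD columns are zero.
    """
    traj, _ = true_trajectory(spec, params, config)
    days = np.arange(0.0, spec.duration_d + 1e-9, spec.sampling_interval_d)
    lengths, weights = traj.sample(days)

    n = spec.n_per_sampling
    if spec.obs_cv == 0:
        zeros = np.zeros_like(days)
        return GrowthObservations(days, lengths, weights, zeros, zeros,
                                  np.full(days.size, n))

    rng = _rng(spec.seed, 1)
    sigma = math.sqrt(math.log(1.0 + spec.obs_cv ** 2))
    mean_l = np.empty(days.size)
    sd_l = np.empty(days.size)
    mean_w = np.empty(days.size)
    sd_w = np.empty(days.size)
    for i in range(days.size):
        draws_l = lengths[i] * np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))
        draws_w = weights[i] * np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))
        mean_l[i], sd_l[i] = draws_l.mean(), draws_l.std(ddof=1)
        mean_w[i], sd_w[i] = draws_w.mean(), draws_w.std(ddof=1)
    return GrowthObservations(days, mean_l, mean_w, sd_l, sd_w,
                              np.full(days.size, n))


def gen_zero_variate_bundle(params: DEBParams, perturbation: float = 0.0,
                            seed: int = 0) -> DataBundle:
    """Bundle of the seven reference-shaped zero-variate entries whose
    observed values are the model's own predictions under ``params``,
    optionally perturbed multiplicatively (relative SD ``perturbation``).

    With perturbation 0 the bundle MRE is exactly zero at ``params``,
    which makes it the ground truth for estimator recovery tests.
    """
    from .estimation import REFERENCE_ZERO_VARIATE

    rng = _rng(seed, 2)
    entries = []
    for ref in REFERENCE_ZERO_VARIATE:
        value = _predict_zero_variate(ref.name, params, ref.temperature_C)
        if perturbation > 0:
            value *= max(1e-6, 1.0 + perturbation * rng.standard_normal())
        entries.append(ZeroVariateEntry(ref.name, float(value), ref.units,
                                        ref.temperature_C, 1.0, ref.label))
    return DataBundle(zero_variate=entries)
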