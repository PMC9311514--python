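"""Covariation parameter estimation and the scalar functional-response fit.

The estimation loop follows the Add-my-Pet recipe in simplified form: a
bundle of zero-variate life-history numbers and univariate growth curves is
compared against model predictions, a weighted mean relative error (MRE) is
minimized with a Nelder–Mead simplex over the chosen free parameters, and
the overall fit is summarized by MRE and the bounded symmetric mean squared
error (SMSE).  Pseudo-data priors and their weighting machinery are out of
scope; all weights default to 1.

The SMSE adopted here is the per-datum bounded form
(p − d)² / (p² + d²) averaged with weights, which lies in [0, 1] and is
zero iff every prediction is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEBError,
    DEBParams,
    ForcingSeries,
    InvalidInput,
    OrganismState,
    structure_from_length,
)
from .simulator import (
    SimConfig,
    Trajectory,
    egg_to_birth,
    integrate,
    life_span,
    reproduction_rate,
    solve_initial_reserve,
    time_to_puberty,
    zero_variate_predictions,
)

__all__ = [
    "loss_mre",
    "loss_smse",
    "nelder_mead",
    "NelderMeadResult",
    "fit_f",
    "ZeroVariateEntry",
    "UnivariateEntry",
    "DataBundle",
    "EstimationResult",
    "estimate_parameters",
    "predict_bundle",
    "reference_zero_variate_observations",
    "REFERENCE_ZERO_VARIATE",
]


# Relative error charged to a bundle entry whose prediction does not exist
# for a candidate parameter set (keeps the estimation objective finite).
INFEASIBLE_PENALTY = 1e3


# ---------------------------------------------------------------------------
# loss functions


def _as_weights(weights, n) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise InvalidInput("weights must match the number of data points")
    if np.any(w < 0):
        raise InvalidInput("weights must be nonnegative")
    if w.sum() == 0:
        raise InvalidInput("at least one weight must be positive")
    return w


def loss_mre(predictions, observations, weights=None) -> float:
    """Weighted mean relative error, Σ w·|p − d|/|d| / Σ w."""
    p = np.asarray(predictions, dtype=float)
    d = np.asarray(observations, dtype=float)
    if p.shape != d.shape or p.ndim != 1:
        raise InvalidInput("predictions and observations must be equal-length 1-D")
    if np.any(d == 0):
        raise InvalidInput("MRE undefined for zero observations")
    w = _as_weights(weights, len(d))
    return float(np.sum(w * np.abs(p - d) / np.abs(d)) / np.sum(w))


def loss_smse(predictions, observations, weights=None) -> float:
    """Weighted symmetric mean squared error, Σ w·(p−d)²/(p²+d²) / Σ w ∈ [0, 1]."""
    p = np.asarray(predictions, dtype=float)
    d = np.asarray(observations, dtype=float)
    if p.shape != d.shape or p.ndim != 1:
        raise InvalidInput("predictions and observations must be equal-length 1-D")
    denom = p * p + d * d
    if np.any(denom == 0):
        raise InvalidInput("SMSE undefined when a prediction and observation are both zero")
    w = _as_weights(weights, len(d))
    return float(np.sum(w * (p - d) ** 2 / denom) / np.sum(w))


# ---------------------------------------------------------------------------
# Nelder–Mead simplex


@dataclass
class NelderMeadResult:
    x: np.ndarray
    fun: float
    trace: list          # best objective value after each iteration
    iterations: int
    converged: bool


def _reflect_into_box(x: np.ndarray, bounds) -> np.ndarray:
    if bounds is None:
        return x
    out = x.copy()
    for i, (lo, hi) in enumerate(bounds):
        if out[i] < lo:
            out[i] = lo + (lo - out[i])
        if out[i] > hi:
            out[i] = hi - (out[i] - hi)
        out[i] = min(max(out[i], lo), hi)  # in case the reflection overshot
    return out


def nelder_mead(objective, x0, bounds=None, *, max_iter=None, tol=1e-8,
                seed=None) -> NelderMeadResult:
    """Derivative-free simplex minimization (Lagarias et al. coefficients).

    Reflection 1, expansion 2, contraction 0.5, shrink 0.5; the initial
    simplex perturbs each coordinate by 5% of |x0_i| (0.0025 absolute when
    the coordinate is zero).  Box bounds are enforced by reflecting a
    trial point back into the box.  Fully deterministic; ``seed`` is
    accepted for interface symmetry and unused.
    """
    del seed
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    if max_iter is None:
        max_iter = 200 * n

    def f(x):
        v = objective(np.asarray(x, dtype=float))
        return float(v) if math.isfinite(v) else math.inf

    simplex = [x0.copy()]
    for i in range(n):
        xi = x0.copy()
        xi[i] = xi[i] * 1.05 if xi[i] != 0.0 else 0.0025
        simplex.append(_reflect_into_box(xi, bounds))
    fvals = [f(x) for x in simplex]
    if not any(math.isfinite(v) for v in fvals):
        raise InvalidInput("objective non-finite on the entire initial simplex")

    alpha, gamma, beta, sigma = 1.0, 2.0, 0.5, 0.5
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(fvals, kind="stable")
        simplex = [simplex[k] for k in order]
        fvals = [fvals[k] for k in order]
        trace.append(fvals[0])

        if (abs(fvals[-1] - fvals[0]) <= tol
                and max(np.max(np.abs(s - simplex[0])) for s in simplex) <= tol):
            converged = True
            break

        centroid = np.mean(simplex[:-1], axis=0)
        xr = _reflect_into_box(centroid + alpha * (centroid - simplex[-1]), bounds)
        fr = f(xr)
        if fr < fvals[0]:
            xe = _reflect_into_box(centroid + gamma * (xr - centroid), bounds)
            fe = f(xe)
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:
                xc = _reflect_into_box(centroid + beta * (xr - centroid), bounds)
            else:
                xc = _reflect_into_box(centroid + beta * (simplex[-1] - centroid), bounds)
            fc = f(xc)
            if fc < min(fr, fvals[-1]):
                simplex[-1], fvals[-1] = xc, fc
            else:
                for k in range(1, n + 1):
                    simplex[k] = simplex[0] + sigma * (simplex[k] - simplex[0])
                    fvals[k] = f(simplex[k])

    order = np.argsort(fvals, kind="stable")
    best = order[0]
    return NelderMeadResult(x=simplex[best].copy(), fun=fvals[best],
                            trace=trace, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# functional-response fit


def _growth_predictions(obs, params: DEBParams, forcing_T: ForcingSeries,
                        f: float, config: SimConfig | None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate from the first observation and sample lengths/weights at obs days.

    Initial state convention for stocked post-larvae: structure from the
    first observed length, reserve at the equilibrium density f·[EM],
    maturity at the metamorphosis threshold.
    """
    days = np.asarray(obs.day, dtype=float)
    v0 = structure_from_length(float(obs.length_cm[0]), params)
    state = OrganismState(E=f * params.EM * v0, V=v0, EH=params.EHj, sex="female")
    cfg = config or SimConfig()
    cfg = SimConfig(t0=float(days[0]), t_end=float(days[-1]), dt=cfg.dt,
                    integrator=cfg.integrator, starvation=cfg.starvation,
                    acceleration=cfg.acceleration, aging=cfg.aging)
    forcing = ForcingSeries(forcing_T.times, forcing_T.temperature_K, f=f)
    traj = integrate(state, forcing, params, cfg)
    return traj.sample(days)


def fit_f(observations, params: DEBParams, forcing_temperature: ForcingSeries,
          config: SimConfig | None = None, tol: float = 1e-4) -> float:
    """Estimate the constant scaled functional response f from growth data.

    Minimizes the combined length + weight MRE over f ∈ [0, 1] by
    golden-section search (deterministic, derivative-free).  Requires at
    least three sampling times.
    """
    days = np.asarray(observations.day, dtype=float)
    if days.size < 3:
        raise InvalidInput("fit_f requires observations at >= 3 time points")

    obs_vec = np.concatenate([np.asarray(observations.length_cm, float),
                              np.asarray(observations.weight_g, float)])

    def objective(f: float) -> float:
        lengths, weights = _growth_predictions(observations, params,
                                               forcing_temperature, f, config)
        return loss_mre(np.concatenate([lengths, weights]), obs_vec)

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.0, 1.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    f_lo, f_hi = objective(a), objective(b)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    candidates = [(f_lo, 0.0), (fc, c), (fd, d), (f_hi, 1.0)]
    best, f_hat = min(candidates)
    if max(v for v, _ in candidates) - best < 1e-12:
        warnings.warn("fit_f objective is flat; observations may be degenerate")
    return float(f_hat)


# ---------------------------------------------------------------------------
# data bundle and the covariation loop


@dataclass
class ZeroVariateEntry:
    """One life-history number: a name from the predictor registry, the
    observed value, its units and (where relevant) the temperature in °C."""

    name: str
    observed: float
    units: str = ""
    temperature_C: float | None = None
    weight: float = 1.0
    label: str = ""


@dataclass
class UnivariateEntry:
    """One growth curve: observations plus the forcing under which to predict."""

    name: str
    observations: object               # GrowthObservations
    quantity: str                      # "length" | "weight" | "both"
    temperature_C: float | None = None
    forcing: ForcingSeries | None = None
    f: float = 1.0
    weight: float = 1.0


@dataclass
class DataBundle:
    zero_variate: list = field(default_factory=list)
    univariate: list = field(default_factory=list)


@dataclass
class EstimationResult:
    params: DEBParams
    free_names: list
    loss: float
    mre: float
    smse: float
    iterations: int
    converged: bool
    seed: int | None = None
    warnings: list = field(default_factory=list)


# Reference life-history observations for kuruma shrimp (literature records):
# observed ages/lengths/weights the default parameter set was estimated from.
REFERENCE_ZERO_VARIATE = [
    ZeroVariateEntry("ab", 2.00, "d", 27.0, label="age at birth (27 °C)"),
    ZeroVariateEntry("am", 730.0, "d", 22.0, label="life span (22 °C)"),
    ZeroVariateEntry("tp", 70.00, "d", 26.0, label="time since birth at puberty (26 °C)"),
    ZeroVariateEntry("Li", 27.00, "cm", None, label="ultimate total length, female"),
    ZeroVariateEntry("Lim", 17.00, "cm", None, label="ultimate total length, male"),
    ZeroVariateEntry("Wwi", 130.0, "g", None, label="ultimate wet weight"),
    ZeroVariateEntry("Ri", 1507.0, "#/d", 27.0, label="ultimate reproduction rate (27 °C)"),
]


def reference_zero_variate_observations() -> DataBundle:
    """Bundle of the reference zero-variate observations (weights all 1)."""
    import copy

    return DataBundle(zero_variate=copy.deepcopy(REFERENCE_ZERO_VARIATE))


def _predict_zero_variate(name: str, params: DEBParams,
                          temperature_C: float | None) -> float:
    from .core import temp_correction, ultimate_length, ultimate_state, wet_weight

    T = None if temperature_C is None else 273.15 + temperature_C
    if name == "ab":
        e0 = solve_initial_reserve(params, T)
        ab, _ = egg_to_birth(params, T, e0)
        return ab
    if name == "am":
        return life_span(params, T)
    if name == "tp":
        return time_to_puberty(params, T)
    if name == "Li":
        return ultimate_length(1.0, params, "female")
    if name == "Lim":
        return ultimate_length(1.0, params, "male")
    if name == "Wwi":
        return wet_weight(ultimate_state(params, 1.0, "female"), params)
    if name == "Ri":
        e0 = solve_initial_reserve(params, T)
        return reproduction_rate(ultimate_state(params, 1.0, "female"),
                                 temp_correction(T, params), params, e0)
    raise InvalidInput(f"no predictor registered for zero-variate entry {name!r}")


def predict_bundle(params: DEBParams, bundle: DataBundle,
                   config: SimConfig | None = None, strict: bool = True):
    """(predictions, observations, weights) arrays aligned across the bundle.

    Zero-variate entries contribute one triple each; univariate entries
    contribute one per sampling time and quantity, with the entry weight
    spread evenly over its points so each curve counts once.  With
    ``strict=False`` an entry whose prediction does not exist for these
    parameters (e.g. puberty never reached) yields NaN instead of raising,
    so an optimizer can penalize it and move on.
    """
    preds, obs, wts = [], [], []
    for entry in bundle.zero_variate:
        try:
            pred = _predict_zero_variate(entry.name, params, entry.temperature_C)
        except DEBError:
            if strict:
                raise
            pred = math.nan
        preds.append(pred)
        obs.append(entry.observed)
        wts.append(entry.weight)
    for entry in bundle.univariate:
        if entry.forcing is not None:
            forcing_T = entry.forcing
        elif entry.temperature_C is not None:
            days = np.asarray(entry.observations.day, float)
            forcing_T = ForcingSeries.constant(273.15 + entry.temperature_C,
                                               entry.f, days[0], days[-1])
        else:
            raise InvalidInput(f"univariate entry {entry.name!r} needs a "
                               "temperature or a forcing series")
        lengths, weights_g = _growth_predictions(entry.observations, params,
                                                 forcing_T, entry.f, config)
        pairs = []
        if entry.quantity in ("length", "both"):
            pairs += list(zip(lengths, np.asarray(entry.observations.length_cm, float)))
        if entry.quantity in ("weight", "both"):
            pairs += list(zip(weights_g, np.asarray(entry.observations.weight_g, float)))
        if not pairs:
            raise InvalidInput(f"univariate entry {entry.name!r} has unknown "
                               f"quantity {entry.quantity!r}")
        w_each = entry.weight / len(pairs)
        for p_i, d_i in pairs:
            preds.append(p_i)
            obs.append(d_i)
            wts.append(w_each)
    return np.asarray(preds), np.asarray(obs), np.asarray(wts)


def estimate_parameters(bundle: DataBundle, free_names, params0: DEBParams,
                        options: dict | None = None) -> EstimationResult:
    """Covariation estimation: minimize the bundle MRE over the free parameters.

    ``free_names`` is a subset of the parameter field names; the remaining
    parameters stay at their ``params0`` values (``muE`` is carried over
    unchanged rather than recalibrated, so the loss surface is smooth in
    the free parameters).  Bounds default to [0.2x, 5x] of the starting
    value of each free parameter.
    """
    opts = dict(options or {})
    free_names = list(free_names)
    valid = set(DEBParams.default().to_dict())
    for name in free_names:
        if name not in valid:
            raise InvalidInput(f"unknown free parameter {name!r}")

    warn_list: list[str] = []

    def with_free(x) -> DEBParams:
        return params0.replace(**{n: float(v) for n, v in zip(free_names, x)})

    def penalized_mre(params: DEBParams) -> float:
        # entries whose prediction does not exist contribute a relative
        # error of INFEASIBLE_PENALTY so the rest of the bundle still
        # steers the simplex back into the feasible region
        p, d, w = predict_bundle(params, bundle, strict=False)
        bad = ~np.isfinite(p)
        p = np.where(bad, d * (1.0 + INFEASIBLE_PENALTY), p)
        return loss_mre(p, d, w)

    def objective(x) -> float:
        try:
            return penalized_mre(with_free(x))
        except (DEBError, ValueError, RuntimeError, ArithmeticError):
            return math.inf

    mre0 = penalized_mre(params0)
    p0, d0, w0 = predict_bundle(params0, bundle, strict=False)

    p0 = np.where(np.isfinite(p0), p0, d0 * (1.0 + INFEASIBLE_PENALTY))
    if not free_names:
        return EstimationResult(params=params0, free_names=[], loss=mre0,
                                mre=mre0, smse=loss_smse(p0, d0, w0),
                                iterations=0, converged=True,
                                seed=opts.get("seed"))

    x0 = np.array([getattr(params0, n) for n in free_names], dtype=float)
    bounds = opts.get("bounds") or [(0.2 * v, 5.0 * v) for v in x0]
    res = nelder_mead(objective, x0, bounds,
                      max_iter=opts.get("max_iter", 250 * len(free_names)),
                      tol=opts.get("tol", 1e-9), seed=opts.get("seed"))
    if res.fun > mre0:  # optimizer contract: never worse than the start
        res.x, res.fun = x0, mre0
        warn_list.append("optimizer did not improve on the starting point")
    best = with_free(res.x)
    p1, d1, w1 = predict_bundle(best, bundle)
    return EstimationResult(params=best, free_names=free_names,
                            loss=float(res.fun), mre=loss_mre(p1, d1, w1),
                            smse=loss_smse(p1, d1, w1),
                            iterations=res.iterations, converged=res.converged,
                            seed=opts.get("seed"), warnings=warn_list)
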