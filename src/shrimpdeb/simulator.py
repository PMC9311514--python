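"""Time integration of the DEB state equations and life-history predictions.

A fixed-step RK4 integrator (default dt = 0.1 d) advances the state under
temperature and food forcing, labels life stages from the maturity
thresholds, and applies the starvation rule.  On top of it sit the
life-history operations: embryo development to birth, the initial-reserve
condition, reproduction rate, time to puberty and (via the aging module)
expected life span — together these produce the zero-variate predictions of
the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEBError,
    DEBParams,
    ForcingCoverageError,
    ForcingSeries,
    IntegrationFailure,
    InvalidInput,
    OrganismState,
    _derivs_raw,
    length_from_structure,
    temp_correction,
    ultimate_state,
    wet_weight,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "integrate",
    "egg_to_birth",
    "solve_initial_reserve",
    "reproduction_rate",
    "time_to_puberty",
    "life_span",
    "zero_variate_predictions",
]

STAGES = ("embryo", "juvenile-prej", "juvenile", "adult")


@dataclass
class SimConfig:
    """Integrator settings (artifact plumbing, not biology)."""

    t0: float = 0.0
    t_end: float = 180.0
    dt: float = 0.1
    integrator: str = "rk4"      # "rk4" | "euler"
    starvation: bool = True
    acceleration: bool = False   # abj-style pAm scaling between birth and metamorphosis
    aging: bool = False
    seed: int | None = None      # reserved; the simulator itself is deterministic

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInput(f"dt must be positive, got {self.dt!r}")
        if self.t_end <= self.t0:
            raise InvalidInput("t_end must exceed t0")
        if self.integrator not in ("rk4", "euler"):
            raise InvalidInput(f"unknown integrator {self.integrator!r}")


@dataclass
class Trajectory:
    """Simulated states over time plus the derived observables."""

    times: np.ndarray
    E: np.ndarray
    V: np.ndarray
    EH: np.ndarray
    ER: np.ndarray
    q: np.ndarray
    h: np.ndarray
    stage: list
    sex: str
    params: DEBParams
    death_day: float | None = None

    @property
    def lengths(self) -> np.ndarray:
        return self.V ** (1.0 / 3.0) / self.params.deltaM

    @property
    def wet_weights(self) -> np.ndarray:
        return (self.E + self.params.kappaR * self.ER) / self.params.muE \
            + self.V * self.params.rho

    def state_at(self, i: int) -> OrganismState:
        return OrganismState(E=float(self.E[i]), V=float(self.V[i]),
                             EH=float(self.EH[i]), ER=float(self.ER[i]),
                             q=float(self.q[i]), h=float(self.h[i]), sex=self.sex)

    def final_state(self) -> OrganismState:
        return self.state_at(len(self.times) - 1)

    def sample(self, days) -> tuple[np.ndarray, np.ndarray]:
        """(length cm, wet weight g) linearly interpolated at the given days."""
        days = np.asarray(days, dtype=float)
        return (np.interp(days, self.times, self.lengths),
                np.interp(days, self.times, self.wet_weights))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_d": self.times,
            "E_J": self.E,
            "V_cm3": self.V,
            "EH_J": self.EH,
            "ER_J": self.ER,
            "length_cm": self.lengths,
            "wetweight_g": self.wet_weights,
            "stage": self.stage,
        })


def _stage_of(EH: float, p: DEBParams) -> str:
    if EH < p.EHb:
        return "embryo"
    if EH < p.EHj:
        return "juvenile-prej"
    if EH < p.EHp:
        return "juvenile"
    return "adult"


def integrate(initial: OrganismState, forcing: ForcingSeries,
              params: DEBParams, config: SimConfig) -> Trajectory:
    """Advance the state from t0 to t_end under the given forcing.

    Forcing is linearly interpolated between its sample points and must
    cover the whole window.  Life-stage transitions follow the maturity
    thresholds and are irreversible (maturity never decreases).  With the
    starvation rule enabled the individual is declared dead when reserve
    and reproduction buffer are exhausted and structure has shrunk below
    80% of its maximum attained value; the trajectory is truncated there.
    """
    cfg = config
    if not forcing.covers(cfg.t0, cfg.t_end):
        raise ForcingCoverageError(
            f"forcing [{forcing.times[0]}, {forcing.times[-1]}] does not cover "
            f"[{cfg.t0}, {cfg.t_end}]"
        )

    n_steps = int(math.ceil((cfg.t_end - cfg.t0) / cfg.dt - 1e-12))
    times = np.empty(n_steps + 1)
    out = {k: np.empty(n_steps + 1) for k in ("E", "V", "EH", "ER", "q", "h")}
    stages: list[str] = []

    p = params
    sex = initial.sex
    y = [initial.E, initial.V, initial.EH, initial.ER, initial.q, initial.h]
    t = cfg.t0
    v_max = y[1]
    death_day = None

    # abj acceleration bookkeeping: pAm scaled by L/Lb between birth and
    # metamorphosis, frozen at Lj/Lb afterwards.  If the run starts after
    # birth the starting length is used as the birth length.
    lb = None
    sm_frozen = None
    if cfg.acceleration and initial.EH >= p.EHb:
        lb = initial.V ** (1.0 / 3.0)
        if initial.EH >= p.EHj:
            sm_frozen = 1.0

    def s_M(EH: float, V: float) -> float:
        nonlocal lb, sm_frozen
        if not cfg.acceleration or EH < p.EHb:
            return 1.0
        if lb is None:
            lb = V ** (1.0 / 3.0)
        if sm_frozen is not None:
            return sm_frozen
        sm = max(1.0, V ** (1.0 / 3.0) / lb)
        if EH >= p.EHj:
            sm_frozen = sm
        return sm

    def rhs(ti: float, yi: list) -> tuple:
        T, f = forcing.at(min(ti, cfg.t_end))
        d = _derivs_raw(yi[0], max(yi[1], 1e-300), yi[2], yi[3], yi[4], yi[5],
                        T, f, p, sex, s_M(yi[2], yi[1]), cfg.starvation, cfg.aging)
        return d[:6]

    for i in range(n_steps + 1):
        times[i] = t
        for j, k in enumerate(("E", "V", "EH", "ER", "q", "h")):
            out[k][i] = y[j]
        stages.append(_stage_of(y[2], p))
        if i == n_steps:
            break

        dt = min(cfg.dt, cfg.t_end - t)
        if cfg.integrator == "euler":
            k1 = rhs(t, y)
            y = [y[j] + dt * k1[j] for j in range(6)]
        else:
            k1 = rhs(t, y)
            y2 = [y[j] + 0.5 * dt * k1[j] for j in range(6)]
            k2 = rhs(t + 0.5 * dt, y2)
            y3 = [y[j] + 0.5 * dt * k2[j] for j in range(6)]
            k3 = rhs(t + 0.5 * dt, y3)
            y4 = [y[j] + dt * k3[j] for j in range(6)]
            k4 = rhs(t + dt, y4)
            y = [y[j] + dt / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                 for j in range(6)]
        t = cfg.t0 + (i + 1) * cfg.dt if i + 1 < n_steps else cfg.t_end

        y[0] = max(y[0], 0.0)  # reserve and buffer cannot go negative
        y[3] = max(y[3], 0.0)
        if not all(math.isfinite(v) for v in y):
            raise IntegrationFailure(f"non-finite state at t = {t:.4f} d")
        if y[1] <= 0:
            raise IntegrationFailure(f"structure collapsed at t = {t:.4f} d")
        v_max = max(v_max, y[1])
        # death: reserve effectively exhausted (scaled density < 1e-6),
        # buffer empty, and structure shrunk below 80% of its maximum
        if (cfg.starvation and y[0] <= 1e-6 * p.EM * y[1] and y[3] <= 1e-9
                and y[1] < 0.8 * v_max):
            death_day = t
            n_trunc = i + 2
            times = times[:n_trunc]
            times[-1] = t
            for j, k in enumerate(("E", "V", "EH", "ER", "q", "h")):
                out[k] = out[k][:n_trunc]
                out[k][-1] = y[j]
            stages.append(_stage_of(y[2], p))
            break

    return Trajectory(times=times, E=out["E"], V=out["V"], EH=out["EH"],
                      ER=out["ER"], q=out["q"], h=out["h"], stage=stages,
                      sex=sex, params=params, death_day=death_day)


# ---------------------------------------------------------------------------
# embryo development and life-history quantities


def egg_to_birth(params: DEBParams, T: float, E0: float,
                 dt: float = 0.005, t_max: float = 60.0,
                 sex: str = "female") -> tuple[float, OrganismState]:
    """Develop an egg of initial reserve E0 at constant temperature until birth.

    The embryo does not feed; reserve fuels maintenance, growth of
    structure and maturation until maturity reaches EHb.  The crossing time
    is located by linear interpolation within the step.  Raises if the
    reserve runs out before birth.
    """
    p = params
    if E0 <= p.EHb:
        raise InvalidInput("E0 must exceed the maturity energy at birth")
    y = [float(E0), 1e-9, 0.0, 0.0, 0.0, 0.0]
    t = 0.0
    while t < t_max:
        prev = (t, list(y))
        k1 = _derivs_raw(*y, T, 0.0, p, sex)[:6]
        y2 = [y[j] + 0.5 * dt * k1[j] for j in range(6)]
        k2 = _derivs_raw(*y2, T, 0.0, p, sex)[:6]
        y3 = [y[j] + 0.5 * dt * k2[j] for j in range(6)]
        k3 = _derivs_raw(*y3, T, 0.0, p, sex)[:6]
        y4 = [y[j] + dt * k3[j] for j in range(6)]
        k4 = _derivs_raw(*y4, T, 0.0, p, sex)[:6]
        y = [y[j] + dt / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
             for j in range(6)]
        t += dt
        if y[0] <= 0.0:
            raise DEBError(
                f"reserve exhausted at t = {t:.3f} d before reaching EHb; "
                "E0 too small"
            )
        if y[2] >= p.EHb:
            t0, y0 = prev
            w = (p.EHb - y0[2]) / (y[2] - y0[2])
            tb = t0 + w * (t - t0)
            yb = [y0[j] + w * (y[j] - y0[j]) for j in range(6)]
            state = OrganismState(E=yb[0], V=yb[1], EH=p.EHb, ER=0.0, sex=sex)
            return tb, state
    raise DEBError(f"maturity did not reach EHb within {t_max} d")


def solve_initial_reserve(params: DEBParams, T: float,
                          rtol: float = 1e-5) -> float:
    """Initial egg reserve E0 such that reserve density at birth equals [EM].

    Standard maternal-effect condition: a well-fed mother provisions eggs so
    the hatchling starts at the equilibrium reserve density of f = 1.
    Solved by bracketing and Brent root finding on e(birth) − 1; the result
    is cached per temperature on the parameter object.
    """
    from scipy.optimize import brentq

    key = round(float(T), 6)
    if key in params._e0_cache:
        return params._e0_cache[key]

    p = params

    def excess(E0: float) -> float:
        try:
            _, state = egg_to_birth(p, T, E0)
        except DEBError:
            return -1.0
        return state.E / state.V / p.EM - 1.0

    lo, hi = p.EHb * 2.0, 1.0
    while excess(hi) < 0.0:
        hi *= 2.0
        if hi > 1e6:
            raise DEBError("failed to bracket the initial reserve from above")
    while excess(lo) > 0.0:
        lo *= 0.5
        if lo < 1e-12:
            raise DEBError("failed to bracket the initial reserve from below")
    e0 = float(brentq(excess, lo, hi, rtol=rtol))
    params._e0_cache[key] = e0
    return e0


def reproduction_rate(state: OrganismState, TC: float, params: DEBParams,
                      E0: float) -> float:
    """Egg production rate κ_R·((1−κ)·p_C − p_J)/E0 (eggs d⁻¹) of an adult."""
    if state.EH < params.EHp:
        raise InvalidInput("reproduction rate is defined for adult states only")
    if E0 <= 0:
        raise InvalidInput("E0 must be positive")
    from .core import catabolic_flux, maturity_maintenance_flux

    pc = catabolic_flux(state, TC, params)
    pj = maturity_maintenance_flux(state, TC, params)
    return params.kappaR * max(0.0, (1.0 - params.kappa) * pc - pj) / E0


def time_to_puberty(params: DEBParams, T: float, f: float = 1.0,
                    dt: float = 0.25, t_max: float = 4000.0,
                    chunk: float = 100.0) -> float:
    """Days from birth until maturity reaches EHp, at constant T and f.

    Integrated in chunks so the run stops shortly after the crossing.
    """
    e0 = solve_initial_reserve(params, T)
    _, birth = egg_to_birth(params, T, e0)
    forcing = ForcingSeries.constant(T, f, 0.0, t_max)
    t0 = 0.0
    state = birth
    while t0 < t_max:
        t1 = min(t0 + chunk, t_max)
        traj = integrate(state, forcing, params,
                         SimConfig(t0=t0, t_end=t1, dt=dt))
        if traj.EH[-1] >= params.EHp:
            idx = int(np.searchsorted(traj.EH, params.EHp))
            if idx == 0:
                return float(traj.times[0])
            w = (params.EHp - traj.EH[idx - 1]) / (traj.EH[idx] - traj.EH[idx - 1])
            return float(traj.times[idx - 1]
                         + w * (traj.times[idx] - traj.times[idx - 1]))
        state = traj.final_state()
        t0 = t1
    raise DEBError(f"puberty not reached within {t_max} d at T = {T} K")


def life_span(params: DEBParams, T: float, f: float = 1.0,
              dt: float = 1.0, t_max: float = 6000.0) -> float:
    """Expected life span (d) at constant T and f from the aging module.

    Integrates the damage-induction states alongside growth from birth,
    converts the hazard h(t) into a survival curve S(t) = exp(−∫h) and
    returns the mean age at death, age at birth included.
    """
    e0 = solve_initial_reserve(params, T)
    ab, birth = egg_to_birth(params, T, e0)
    forcing = ForcingSeries.constant(T, f, 0.0, t_max)
    traj = integrate(birth, forcing, params,
                     SimConfig(t0=0.0, t_end=t_max, dt=dt, aging=True))
    cumhaz = np.concatenate([[0.0], np.cumsum(
        0.5 * (traj.h[1:] + traj.h[:-1]) * np.diff(traj.times))])
    survival = np.exp(-cumhaz)
    if survival[-1] > 1e-3:
        raise DEBError("survival has not decayed by t_max; increase t_max")
    return float(ab + np.trapezoid(survival, traj.times))


def zero_variate_predictions(params: DEBParams, dt_embryo: float = 0.002) -> dict:
    """The model's single-number life-history predictions.

    Returns a dict keyed by the conventional symbols: age at birth ``ab``
    (d, 27 °C), life span ``am`` (d, 22 °C), time since birth at puberty
    ``tp`` (d, 26 °C), ultimate physical lengths ``Li``/``Lim`` (cm,
    female/male), ultimate wet weight ``Wwi`` (g) and ultimate reproduction
    rate ``Ri`` (eggs d⁻¹, 27 °C).
    """
    from .core import ultimate_length

    T27, T26, T22 = 273.15 + 27.0, 273.15 + 26.0, 273.15 + 22.0
    e0_27 = solve_initial_reserve(params, T27)
    ab, _ = egg_to_birth(params, T27, e0_27, dt=dt_embryo)
    ult = ultimate_state(params, f=1.0, sex="female")
    tc27 = temp_correction(T27, params)
    return {
        "ab": ab,
        "am": life_span(params, T22),
        "tp": time_to_puberty(params, T26),
        "Li": ultimate_length(1.0, params, "female"),
        "Lim": ultimate_length(1.0, params, "male"),
        "Wwi": wet_weight(ult, params),
        "Ri": reproduction_rate(ult, tc27, params, e0_27),
    }
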