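"""Core state variables, parameters and energy fluxes of the kuruma shrimp DEB model.

The model tracks an individual shrimp through four state variables — reserve
energy ``E`` (J), structural volume ``V`` (cm³), cumulative maturity ``E_H``
(J) and the reproduction buffer ``E_R`` (J) — plus optional aging states
``q`` (d⁻²) and ``h`` (d⁻¹).  Energy assimilated from food enters the
reserve; mobilized reserve (the catabolic flux) is split by the κ rule: a
fixed fraction ``κ`` pays somatic maintenance and growth, the remaining
``1 − κ`` pays maturity maintenance and maturation (before puberty) or
reproduction (after).  All rates share a single Arrhenius temperature
correction with a tolerance range.

Every flux function takes plain floats and returns J·d⁻¹; the derivative
bundle :func:`state_derivatives` wires them together and is the single place
the κ rule and the starvation convention live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "DEBError",
    "InvalidInput",
    "IntegrationFailure",
    "ForcingCoverageError",
    "DEBParams",
    "OrganismState",
    "ForcingSeries",
    "Derivatives",
    "temp_correction",
    "holling_response",
    "assimilation_flux",
    "catabolic_flux",
    "somatic_maintenance_flux",
    "maturity_maintenance_flux",
    "state_derivatives",
    "energy_fluxes",
    "length_from_structure",
    "structure_from_length",
    "wet_weight",
    "ultimate_length",
    "ultimate_structural_length",
    "aging_hazard_derivatives",
]


class DEBError(Exception):
    """Base class for model errors."""


class InvalidInput(DEBError, ValueError):
    """An argument violates a precondition or type invariant."""


class IntegrationFailure(DEBError, RuntimeError):
    """The state left the admissible region during integration."""


class ForcingCoverageError(DEBError, ValueError):
    """The forcing series does not cover the requested time window."""


# Anchor observations used once, at parameter construction, to back out the
# reserve energy content mu_E from the ultimate-state identity
# Ww_inf = E_inf/mu_E + rho*V_inf (reproduction buffer empty):
# the reference female ultimate physical length and ultimate wet weight.
MU_E_ANCHOR_LENGTH_CM = 19.83
MU_E_ANCHOR_WET_WEIGHT_G = 135.9


@dataclass
class DEBParams:
    """Complete parameter set of the model (reference temperature 20 °C).

    Defaults are the estimated kuruma shrimp values.  ``muE`` (reserve
    energy content, J·g⁻¹) is not part of the published set; when left
    ``None`` it is calibrated once from the ultimate-state identity with the
    anchor length/weight above so that the parameter set is internally
    consistent.  ``v_dot`` is stored for reference only: the flux equations
    mobilize reserve at conductance ``pAm/EM`` (see the catabolic flux),
    which for this set is 0.1377 cm·d⁻¹ and is *not* equal to the printed
    ``v_dot``; the dynamics follow the flux equations.
    """

    z: float = 0.76          # zoom factor, female (-)
    zm: float = 0.71         # zoom factor, male (-)
    Fm_max: float = 6.5      # maximum specific searching rate (J cm-2 d-1)
    v_dot: float = 0.0336    # printed energy conductance (cm d-1), reference only
    EG: float = 4439.0       # volume-specific cost for structure (J cm-3)
    EM: float = 13235.0      # maximum reserve density (J cm-3)
    kappa: float = 0.98      # somatic allocation fraction (-)
    kappaR: float = 0.95     # reproduction efficiency (-)
    deltaM: float = 0.1585   # shape coefficient (-)
    pAm: float = 1823.0      # max surface-specific assimilation rate (J cm-2 d-1)
    pM: float = 569.0        # volume-specific maintenance rate (J cm-3 d-1)
    T1: float = 293.0        # reference temperature (K)
    TA: float = 6200.0       # Arrhenius temperature (K)
    TH: float = 302.0        # upper tolerance boundary (K)
    TL: float = 283.0        # lower tolerance boundary (K)
    TAH: float = 33800.0     # Arrhenius temperature at upper boundary (K)
    TAL: float = 13300.0     # Arrhenius temperature at lower boundary (K)
    rho: float = 1.0         # volume-specific weight density (g cm-3)
    EHb: float = 0.0013      # maturity at birth (J)
    EHj: float = 0.0966      # maturity at metamorphosis (J)
    EHp: float = 2349.0      # maturity at puberty (J)
    ha: float = 1.8e-7       # Weibull aging acceleration (d-2)
    sG: float = 0.0001       # Gompertz stress coefficient (-)
    muE: float | None = None  # reserve energy content (J g-1); calibrated if None
    XK: float | None = None   # half-saturation food density (density units)

    _vp_cache: float | None = field(default=None, repr=False, compare=False)
    _e0_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()
        if self.muE is None:
            va = (MU_E_ANCHOR_LENGTH_CM * self.deltaM) ** 3
            denom = MU_E_ANCHOR_WET_WEIGHT_G - self.rho * va
            if denom <= 0:
                raise InvalidInput(
                    "muE calibration failed: anchor wet weight does not exceed "
                    "the structural mass; supply muE explicitly"
                )
            self.muE = self.EM * va / denom

    def validate(self) -> None:
        positive = (
            "z", "zm", "Fm_max", "v_dot", "EG", "EM", "deltaM", "pAm", "pM",
            "T1", "TA", "TH", "TL", "TAH", "TAL", "rho", "EHb", "EHj", "EHp",
        )
        for name in positive:
            val = getattr(self, name)
            if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                raise InvalidInput(f"parameter {name!r} must be strictly positive, got {val!r}")
        for name in ("ha", "sG"):
            if getattr(self, name) < 0:
                raise InvalidInput(f"parameter {name!r} must be nonnegative")
        if not 0 < self.kappa <= 1:
            raise InvalidInput(f"parameter 'kappa' must be in (0, 1], got {self.kappa!r}")
        if not 0 < self.kappaR <= 1:
            raise InvalidInput(f"parameter 'kappaR' must be in (0, 1], got {self.kappaR!r}")
        if not 0 < self.deltaM < 1:
            raise InvalidInput(f"parameter 'deltaM' must be in (0, 1), got {self.deltaM!r}")
        if not self.TL < self.T1 < self.TH:
            raise InvalidInput("temperature tolerance range requires TL < T1 < TH")
        if not self.EHb < self.EHj < self.EHp:
            raise InvalidInput("maturity thresholds require EHb < EHj < EHp")
        if self.muE is not None and self.muE <= 0:
            raise InvalidInput(f"parameter 'muE' must be strictly positive, got {self.muE!r}")
        if self.XK is not None and self.XK <= 0:
            raise InvalidInput(f"parameter 'XK' must be strictly positive, got {self.XK!r}")

    # -- derived quantities -------------------------------------------------

    def pAm_for(self, sex: str) -> float:
        """Sex-specific assimilation capacity: males carry pAm scaled by zm/z."""
        if sex == "female":
            return self.pAm
        if sex == "male":
            return self.pAm * self.zm / self.z
        raise InvalidInput(f"sex must be 'female' or 'male', got {sex!r}")

    @property
    def conductance(self) -> float:
        """Reserve mobilization conductance implied by the fluxes, pAm/EM (cm d-1)."""
        return self.pAm / self.EM

    @property
    def structure_at_puberty(self) -> float:
        """Structural volume V_P at which maturity first reaches EHp.

        Computed once per parameter set from the reference trajectory
        (f = 1, reserve density at equilibrium), where the temperature
        factor cancels out of the state-space path: maturity is integrated
        against structure from near zero until it crosses ``EHp``.  If the
        asymptotic maturity stays below ``EHp`` the clamp never binds and
        V_P is infinite.
        """
        if self._vp_cache is None:
            self._vp_cache = _compute_structure_at_puberty(self)
        return self._vp_cache

    def replace(self, **changes) -> "DEBParams":
        """Return a validated copy with fields replaced (caches dropped)."""
        changes.setdefault("_vp_cache", None)
        changes.setdefault("_e0_cache", {})
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if not f.name.startswith("_")
        }

    @classmethod
    def default(cls) -> "DEBParams":
        return cls()


def _compute_structure_at_puberty(params: DEBParams) -> float:
    from scipy.integrate import solve_ivp

    p = params
    v_inf = (p.kappa * p.pAm / p.pM) ** 3
    a = p.EM / (p.EG + p.kappa * p.EM)  # mobilization factor at e = 1

    def dEH_dV(v, _eh):
        pc = a * (p.EG * p.pAm * v ** (2.0 / 3.0) / p.EM + p.pM * v)
        growth = (p.kappa * pc - p.pM * v) / p.EG
        maturation = (1.0 - p.kappa) * pc - v * p.pM * (1.0 - p.kappa) / p.kappa
        return maturation / growth

    def crossed(v, eh):
        return eh[0] - p.EHp

    crossed.terminal = True
    crossed.direction = 1.0

    sol = solve_ivp(
        dEH_dV, (1e-12, v_inf * (1.0 - 1e-9)), [0.0],
        events=crossed, rtol=1e-10, atol=1e-12, method="RK45",
    )
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return math.inf


@dataclass
class OrganismState:
    """Instantaneous state of one individual."""

    E: float            # reserve energy (J)
    V: float            # structural volume (cm3)
    EH: float = 0.0     # cumulative maturity (J)
    ER: float = 0.0     # reproduction buffer (J)
    q: float = 0.0      # aging acceleration (d-2)
    h: float = 0.0      # hazard rate (d-1)
    sex: str = "female"

    def __post_init__(self) -> None:
        if not (self.V > 0 and math.isfinite(self.V)):
            raise InvalidInput(f"structural volume must be > 0, got {self.V!r}")
        if self.E < 0 or self.EH < 0 or self.ER < 0:
            raise InvalidInput("E, EH and ER must be nonnegative")
        if self.sex not in ("female", "male"):
            raise InvalidInput(f"sex must be 'female' or 'male', got {self.sex!r}")

    def stage(self, params: DEBParams) -> str:
        if self.EH < params.EHb:
            return "embryo"
        if self.EH < params.EHj:
            return "juvenile-prej"
        if self.EH < params.EHp:
            return "juvenile"
        return "adult"


class ForcingSeries:
    """Time-indexed temperature (K) and scaled functional response f.

    Food may be given directly as ``f`` in [0, 1] or as a density ``X``
    together with the half-saturation density ``XK`` (converted through the
    Holling type-II response).  Temperature is linearly interpolated between
    sample points; ``f`` likewise.
    """

    def __init__(self, times, temperature_K, f=None, X=None, XK=None):
        import numpy as np

        self.times = np.asarray(times, dtype=float)
        self.temperature_K = np.asarray(temperature_K, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise InvalidInput("forcing times must be a nonempty 1-D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInput("forcing times must be strictly increasing")
        if self.temperature_K.shape != self.times.shape:
            raise InvalidInput("temperature column length must match times")
        if np.any(self.temperature_K < 270.0) or np.any(self.temperature_K > 320.0):
            raise InvalidInput("temperatures must lie in the plausible range 270-320 K")
        if (f is None) == (X is None):
            raise InvalidInput("supply exactly one of f or X")
        if f is not None:
            self.f = np.broadcast_to(np.asarray(f, dtype=float), self.times.shape).copy()
            self.X = None
        else:
            self.X = np.broadcast_to(np.asarray(X, dtype=float), self.times.shape).copy()
            if XK is None:
                raise InvalidInput("XK is required to convert food density X to f")
            self.f = np.array([holling_response(x, XK) for x in self.X])
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise InvalidInput("f must lie in [0, 1]")

    @classmethod
    def constant(cls, temperature_K: float, f: float, t0: float = 0.0,
                 t_end: float = 1.0) -> "ForcingSeries":
        return cls([t0, t_end], [temperature_K, temperature_K], f=[f, f])

    def covers(self, t0: float, t_end: float) -> bool:
        return self.times[0] <= t0 + 1e-9 and self.times[-1] >= t_end - 1e-9

    def at(self, t: float) -> tuple[float, float]:
        """(temperature K, f) at time t, linearly interpolated."""
        import numpy as np

        if not (self.times[0] - 1e-9 <= t <= self.times[-1] + 1e-9):
            raise ForcingCoverageError(
                f"time {t} outside forcing window [{self.times[0]}, {self.times[-1]}]"
            )
        return (
            float(np.interp(t, self.times, self.temperature_K)),
            float(np.interp(t, self.times, self.f)),
        )


# ---------------------------------------------------------------------------
# response functions


def temp_correction(T: float, params: DEBParams, normalized: bool = False) -> float:
    """Arrhenius temperature factor with a tolerance range.

    Multiplies every physiological rate.  The factor is the plain Arrhenius
    term about the reference temperature ``T1`` damped by the low/high
    boundary terms; as printed it is ~0.811 at ``T1`` itself (the boundary
    terms do not vanish there).  ``normalized=True`` divides by the value at
    ``T1`` so the factor is exactly 1 at the reference temperature.
    """
    if not (isinstance(T, (int, float)) and math.isfinite(T) and T > 0):
        raise InvalidInput(f"temperature must be a positive finite number, got {T!r}")
    p = params
    factor = math.exp(p.TA / p.T1 - p.TA / T) / (
        1.0
        + math.exp(p.TAL / T - p.TAL / p.TL)
        + math.exp(p.TAH / p.TH - p.TAH / T)
    )
    if normalized:
        factor /= 1.0 / (
            1.0
            + math.exp(p.TAL / p.T1 - p.TAL / p.TL)
            + math.exp(p.TAH / p.TH - p.TAH / p.T1)
        )
    return factor


def holling_response(X: float, XK: float) -> float:
    """Holling type-II scaled functional response f = X/(XK + X) in [0, 1)."""
    if not (math.isfinite(X) and X >= 0):
        raise InvalidInput(f"food density X must be nonnegative, got {X!r}")
    if not (math.isfinite(XK) and XK > 0):
        raise InvalidInput(f"half-saturation density XK must be positive, got {XK!r}")
    return X / (XK + X)


# ---------------------------------------------------------------------------
# energy fluxes (all J d-1)


def assimilation_flux(state: OrganismState, f: float, TC: float,
                      params: DEBParams, s_M: float = 1.0) -> float:
    """Assimilation p_A = kT·f·{pAm}·V^(2/3); zero before birth (embryos do not feed)."""
    if not 0.0 <= f <= 1.0:
        raise InvalidInput(f"f must be in [0, 1], got {f!r}")
    if TC <= 0:
        raise InvalidInput(f"temperature factor must be positive, got {TC!r}")
    if state.EH < params.EHb:
        return 0.0
    return TC * f * params.pAm_for(state.sex) * s_M * state.V ** (2.0 / 3.0)


def catabolic_flux(state: OrganismState, TC: float, params: DEBParams,
                   s_M: float = 1.0) -> float:
    """Catabolic (mobilization) power
    p_C = kT · (E/V)/([EG] + κ·E/V) · ([EG]·{pAm}·V^(2/3)/[EM] + [pM]·V)."""
    if state.V <= 0:
        raise InvalidInput("catabolic flux requires V > 0")
    if TC <= 0:
        raise InvalidInput(f"temperature factor must be positive, got {TC!r}")
    mob = state.E / state.V
    pam = params.pAm_for(state.sex) * s_M
    return TC * (mob / (params.EG + params.kappa * mob)) * (
        params.EG * pam * state.V ** (2.0 / 3.0) / params.EM + params.pM * state.V
    )


def somatic_maintenance_flux(state: OrganismState, TC: float,
                             params: DEBParams) -> float:
    """Somatic maintenance p_M = kT·[pM]·V."""
    return TC * params.pM * state.V


def maturity_maintenance_flux(state: OrganismState, TC: float,
                              params: DEBParams) -> float:
    """Maturity maintenance p_J = kT·min(V, V_P)·[pM]·(1-κ)/κ."""
    v_eff = min(state.V, params.structure_at_puberty)
    return TC * v_eff * params.pM * (1.0 - params.kappa) / params.kappa


@dataclass
class Derivatives:
    """Time derivatives of the state plus the fluxes that produced them."""

    dE: float
    dV: float
    dEH: float
    dER: float
    dq: float = 0.0
    dh: float = 0.0
    pA: float = 0.0
    pC: float = 0.0
    pM_flux: float = 0.0
    pJ: float = 0.0


def _derivs_raw(E, V, EH, ER, q, h, T, f, params, sex="female",
                s_M=1.0, starvation=True, aging=False):
    """Fast scalar derivative kernel used by the integrators.

    Implements the κ rule: p_C splits into κ·p_C (somatic maintenance +
    growth at cost EG) and (1-κ)·p_C (maturity maintenance + maturation,
    routed to E_H below puberty and to E_R above it).  Starvation rule:
    when κ·p_C cannot cover somatic maintenance the deficit is paid first
    from the reproduction buffer, then by mobilizing structure at EG per
    unit volume.
    """
    p = params
    TC = temp_correction(T, p)
    pam = p.pAm_for(sex) * s_M
    v23 = V ** (2.0 / 3.0)

    pA = 0.0 if EH < p.EHb else TC * f * pam * v23
    mob = E / V
    pC = TC * (mob / (p.EG + p.kappa * mob)) * (p.EG * pam * v23 / p.EM + p.pM * V)
    pMf = TC * p.pM * V
    pJ = TC * min(V, p.structure_at_puberty) * p.pM * (1.0 - p.kappa) / p.kappa

    growth_power = p.kappa * pC - pMf
    dER_starv = 0.0
    if growth_power >= 0.0 or not starvation:
        dV = growth_power / p.EG
    else:
        deficit = -growth_power
        if ER > 0.0:
            dER_starv = -deficit
            dV = 0.0
        else:
            dV = -deficit / p.EG

    dE = pA - pC
    maturation = (1.0 - p.kappa) * pC - pJ
    if EH < p.EHp:
        dEH = max(0.0, maturation)  # maturity never regresses
        dER = dER_starv
    else:
        dEH = 0.0
        dER = maturation + dER_starv

    dq = dh = 0.0
    if aging:
        e_scaled = mob / p.EM
        L = V ** (1.0 / 3.0)
        r = dV / V
        v_cond = TC * pam / p.EM
        v_m = (p.kappa * pam / p.pM) ** 3
        dq = (q * (V / v_m) * p.sG + p.ha) * e_scaled * (v_cond / L - r) - r * q
        dh = q - r * h

    return dE, dV, dEH, dER, dq, dh, pA, pC, pMf, pJ


def state_derivatives(state: OrganismState, T: float, f: float,
                      params: DEBParams, *, s_M: float = 1.0,
                      starvation: bool = True, aging: bool = False) -> Derivatives:
    """Full derivative bundle at a given temperature (K) and feeding level."""
    if not 0.0 <= f <= 1.0:
        raise InvalidInput(f"f must be in [0, 1], got {f!r}")
    out = _derivs_raw(state.E, state.V, state.EH, state.ER, state.q, state.h,
                      T, f, params, state.sex, s_M, starvation, aging)
    return Derivatives(*out)


def energy_fluxes(state: OrganismState, T: float, f: float,
                  params: DEBParams) -> dict:
    """The four instantaneous powers (pA, pC, pM, pJ) at (T, f), J d-1."""
    d = state_derivatives(state, T, f, params)
    return {"pA": d.pA, "pC": d.pC, "pM": d.pM_flux, "pJ": d.pJ}


def aging_hazard_derivatives(state: OrganismState, T: float, f: float,
                             params: DEBParams) -> tuple[float, float]:
    """(dq/dt, dh/dt) of the Weibull/Gompertz aging module.

    The formulation is the standard DEB damage-induction pair
    dq/dt = (q·(V/Vm)·s_G + h_a)·e·(v/L − r) − r·q and dh/dt = q − r·h,
    with e the scaled reserve density, r the specific growth rate and v the
    mobilization conductance pAm/EM; setting h_a = 0 freezes aging.
    """
    d = state_derivatives(state, T, f, params, aging=True)
    return d.dq, d.dh


# ---------------------------------------------------------------------------
# observables


def length_from_structure(V: float, params: DEBParams) -> float:
    """Physical total length L = V^(1/3)/δ_M (cm)."""
    if V < 0:
        raise InvalidInput(f"structural volume must be nonnegative, got {V!r}")
    return V ** (1.0 / 3.0) / params.deltaM


def structure_from_length(L: float, params: DEBParams) -> float:
    """Structural volume from physical total length, V = (L·δ_M)^3 (cm³)."""
    if L < 0:
        raise InvalidInput(f"length must be nonnegative, got {L!r}")
    return (L * params.deltaM) ** 3


def wet_weight(state: OrganismState, params: DEBParams) -> float:
    """Wet weight Ww = E/μ_E + κ_R·E_R/μ_E + V·ρ (g)."""
    return (state.E + params.kappaR * state.ER) / params.muE + state.V * params.rho


def ultimate_structural_length(f: float, params: DEBParams,
                               sex: str = "female") -> float:
    """Asymptotic structural length f·κ·{pAm}/[pM] (cm) under constant feeding."""
    if not 0.0 <= f <= 1.0:
        raise InvalidInput(f"f must be in [0, 1], got {f!r}")
    return f * params.kappa * params.pAm_for(sex) / params.pM


def ultimate_length(f: float, params: DEBParams, sex: str = "female") -> float:
    """Asymptotic physical total length f·κ·{pAm}/([pM]·δ_M) (cm).

    Exact for the flux system under constant forcing: the asymptote is
    independent of the reserve capacity [EM] and scales linearly in f.
    """
    return ultimate_structural_length(f, params, sex) / params.deltaM


def ultimate_state(params: DEBParams, f: float = 1.0,
                   sex: str = "female") -> OrganismState:
    """Fully grown adult state at feeding level f (reserve at equilibrium density)."""
    v = ultimate_structural_length(f, params, sex) ** 3
    return OrganismState(E=f * params.EM * v, V=v, EH=params.EHp, ER=0.0, sex=sex)
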