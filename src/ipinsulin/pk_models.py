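"""Compartmental models of intraperitoneal (IP) insulin absorption and
whole-body insulin kinetics.

Nine model variants are obtained by crossing three linear models of IP
insulin absorption (M1: one compartment; M2: two compartments in cascade;
M3: two compartments with absorption from both) with three descriptions of
hepatic insulin extraction HE(t) (A: constant; B: modulated by plasma
glucose; C: modulated by hepatic insulin mass).  IP-delivered insulin
appears in the liver compartment of a two-compartment whole-body kinetics
model, reflecting the anatomy of intraperitoneal delivery.

Units: insulin masses in mU, rates in min^-1, infusion in mU/min,
concentrations in mU/L (insulin) and mg/dL (glucose), volumes in L,
clearance in L/min, time in minutes.  Doses given in U are converted at
1 U = 1000 mU; the U-400 formulation affects delivered volume only and is
ignored (mass is what the model tracks).
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger("ipinsulin")

# ---------------------------------------------------------------------------
# Module-wide defaults
# ---------------------------------------------------------------------------

#: Fractional rate of hepatic plasma flow (min^-1); fixed, not estimated —
#: with m2 known all nine variants are structurally identifiable.
M2_DEFAULT = 0.268

#: Default clamp interval for the affine hepatic-extraction laws, which can
#: otherwise leave (0, 1); m3 = HE/(1-HE)*m1 diverges as HE -> 1.
HE_CLAMP_DEFAULT = (0.0, 0.95)

#: Default solver tolerances for high-accuracy simulation.
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10

MILLIUNITS_PER_UNIT = 1000.0


class DegenerateParametersError(ValueError):
    """Raised when a parameter combination is structurally infeasible."""


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid trajectory."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


class AbsorptionVariant(enum.Enum):
    """IP absorption structure: one compartment (M1), two-compartment
    cascade (M2), or two compartments both absorbing to the liver (M3)."""

    M1 = "1"
    M2 = "2"
    M3 = "3"


class HEVariant(enum.Enum):
    """Hepatic-extraction law: constant (A), glucose-controlled (B), or
    controlled by hepatic insulin mass (C)."""

    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine (absorption x hepatic-extraction) model variants."""

    absorption: AbsorptionVariant
    hepatic: HEVariant

    def __str__(self) -> str:
        return f"{self.absorption.value}{self.hepatic.value}"

    @classmethod
    def from_string(cls, s: str) -> "ModelSpec":
        s = s.strip().upper()
        if len(s) != 2:
            raise ValueError(f"model spec must be like '3C', got {s!r}")
        return cls(AbsorptionVariant(s[0]), HEVariant(s[1]))

    @classmethod
    def all_nine(cls) -> list["ModelSpec"]:
        return [cls(a, h) for h in HEVariant for a in AbsorptionVariant]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbsorptionParams:
    """Rate constants of one IP absorption variant (one instance per meal
    period when absorption is allowed to vary meal-by-meal).

    ka1: absorption from the first IP compartment to the liver (M1, M3).
    ka2: absorption from the second IP compartment to the liver (M2, M3).
    kd:  distribution between the two IP compartments (M2 only); the two
         rates are interchangeable, so kd >= ka2 is imposed by convention.
    """

    ka1: float | None = None
    ka2: float | None = None
    kd: float | None = None

    def validate(self, variant: AbsorptionVariant) -> None:
        if variant is AbsorptionVariant.M1:
            _require_rate("ka1", self.ka1, nonneg=False)
        elif variant is AbsorptionVariant.M2:
            _require_rate("ka2", self.ka2, nonneg=False)
            _require_rate("kd", self.kd, nonneg=False)
            if self.kd < self.ka2:
                raise DegenerateParametersError(
                    f"M2 requires kd >= ka2 (got kd={self.kd}, ka2={self.ka2})"
                )
        else:  # M3: ka1 >= 0 (may collapse to exactly zero), ka2 > 0
            _require_rate("ka1", self.ka1, nonneg=True)
            _require_rate("ka2", self.ka2, nonneg=False)


def _require_rate(name: str, value: float | None, nonneg: bool) -> None:
    if value is None or not math.isfinite(value):
        raise DegenerateParametersError(f"{name} must be a finite rate, got {value}")
    if nonneg:
        if value < 0:
            raise DegenerateParametersError(f"{name} must be >= 0, got {value}")
    elif value <= 0:
        raise DegenerateParametersError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class KineticsParams:
    """Whole-body insulin kinetics parameters.

    VI:  insulin distribution volume (L).
    m1:  liver-to-plasma insulin distribution rate (min^-1).
    m2:  fractional hepatic plasma flow (min^-1); fixed by default.
    CL:  post-hepatic insulin clearance (L/min); CL = (HEb*m2 + m4)*VI, so
         the peripheral degradation rate m4 is derived, not stored.
    HEb: basal hepatic insulin extraction, in (0, 1).
    aG:  glucose control on HE (dL/mg, variant B only).
    aI:  hepatic-insulin control on HE (mU^-1, variant C only).
    Gb:  basal plasma glucose (mg/dL, variant B only).
    """

    VI: float
    m1: float
    CL: float
    HEb: float
    m2: float = M2_DEFAULT
    aG: float = 0.0
    aI: float = 0.0
    Gb: float | None = None

    def __post_init__(self) -> None:
        for name in ("VI", "m1", "m2", "CL"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise DegenerateParametersError(f"{name} must be > 0, got {v}")
        if not 0.0 < self.HEb < 1.0:
            raise DegenerateParametersError(f"HEb must be in (0, 1), got {self.HEb}")
        for name in ("aG", "aI"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise DegenerateParametersError(f"{name} must be >= 0, got {v}")
        # fail fast on CL too small to leave a non-negative m4
        derive_m4(self)


def derive_m4(kin: KineticsParams) -> float:
    """Peripheral insulin degradation rate m4 (min^-1), from the clearance
    decomposition CL = (HEb*m2 + m4)*VI."""
    m4 = kin.CL / kin.VI - kin.HEb * kin.m2
    if m4 < 0:
        raise DegenerateParametersError(
            f"CL/VI = {kin.CL / kin.VI:.6g} <= HEb*m2 = {kin.HEb * kin.m2:.6g}: "
            "negative peripheral degradation rate m4"
        )
    return m4


def derive_m3_basal(kin: KineticsParams) -> float:
    """Basal hepatic insulin degradation rate m3b = HEb/(1-HEb)*m1."""
    if not 0.0 < kin.HEb < 1.0:
        raise DegenerateParametersError(f"HEb must be in (0, 1), got {kin.HEb}")
    return kin.HEb / (1.0 - kin.HEb) * kin.m1


def hepatic_extraction(
    he_variant: HEVariant,
    kin: KineticsParams,
    Ql: float | np.ndarray | None = None,
    G: float | np.ndarray | None = None,
    Qlb: float | None = None,
    clamp: tuple[float, float] = HE_CLAMP_DEFAULT,
):
    """Hepatic extraction fraction HE under the given law.

    A: HE = HEb.
    B: HE = -aG*(G - Gb) + HEb  (rises when glucose falls below basal).
    C: HE = -aI*(Ql - Qlb) + HEb  (saturates as hepatic insulin rises).

    The affine laws are clamped to ``clamp`` since m3 diverges as HE -> 1.
    """
    lo, hi = clamp
    if he_variant is HEVariant.A:
        he = kin.HEb if np.isscalar(Ql) or Ql is None else np.full_like(np.asarray(Ql, float), kin.HEb)
    elif he_variant is HEVariant.B:
        if G is None or kin.Gb is None:
            raise ValueError("variant B requires a glucose value G and basal Gb")
        he = -kin.aG * (np.asarray(G, float) - kin.Gb) + kin.HEb
    else:
        if Ql is None or Qlb is None:
            raise ValueError("variant C requires hepatic insulin mass Ql and its basal Qlb")
        he = -kin.aI * (np.asarray(Ql, float) - Qlb) + kin.HEb
    return np.clip(he, lo, hi) if not np.isscalar(he) else min(max(he, lo), hi)


# ---------------------------------------------------------------------------
# Basal steady state
# ---------------------------------------------------------------------------

# State layout used throughout: y = [Qip1, Qip2, Qp, Ql] (mU); Qip2 is held
# at zero for M1.
STATE_NAMES = ("Qip1", "Qip2", "Qp", "Ql")


def basal_steady_state(
    spec: ModelSpec,
    absorption: AbsorptionParams,
    kin: KineticsParams,
    inf_b: float,
) -> np.ndarray:
    """Unique steady state under constant basal infusion ``inf_b`` (mU/min).

    At steady state the absorption flux RaI equals inf_b for every variant,
    and (Qpb, Qlb) solve the linear balance
    (m2+m4)*Qpb = m1*Qlb,  (m1+m3b)*Qlb = m2*Qpb + inf_b.
    All HE laws evaluate to HEb at their own basal point, so the steady
    state is exact for every hepatic-extraction variant.
    """
    if inf_b < 0:
        raise ValueError(f"basal infusion must be >= 0, got {inf_b}")
    absorption.validate(spec.absorption)
    if inf_b == 0.0:
        return np.zeros(4)

    if spec.absorption is AbsorptionVariant.M1:
        qip1, qip2 = inf_b / absorption.ka1, 0.0
    elif spec.absorption is AbsorptionVariant.M2:
        qip1, qip2 = inf_b / absorption.kd, inf_b / absorption.ka2
    else:
        ktot = absorption.ka1 + absorption.ka2
        if ktot <= 0:
            raise DegenerateParametersError("M3 with ka1 + ka2 = 0 has no steady state")
        qip1 = qip2 = inf_b / ktot

    m4 = derive_m4(kin)
    m3b = derive_m3_basal(kin)
    a = np.array([[kin.m2 + m4, -kin.m1], [-kin.m2, kin.m1 + m3b]])
    qpb, qlb = np.linalg.solve(a, np.array([0.0, inf_b]))
    return np.array([qip1, qip2, qpb, qlb])


# ---------------------------------------------------------------------------
# Inputs: infusion and glucose profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InfusionProfile:
    """Piecewise-constant basal infusion plus impulsive boluses.

    ``basal_times``/``basal_rates``: rate ``basal_rates[i]`` (mU/min) holds
    on [basal_times[i], basal_times[i+1]); the last rate holds to the end.
    ``boluses``: (time_min, dose_mU) pairs, delivered into the first IP
    compartment.
    """

    basal_times: tuple[float, ...] = (0.0,)
    basal_rates: tuple[float, ...] = (0.0,)
    boluses: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.basal_times) != len(self.basal_rates):
            raise ValueError("basal_times and basal_rates must have equal length")
        if any(r < 0 for r in self.basal_rates):
            raise ValueError("basal rates must be >= 0")
        if list(self.basal_times) != sorted(self.basal_times):
            raise ValueError("basal_times must be sorted")
        if any(d < 0 for _, d in self.boluses):
            raise ValueError("bolus doses must be >= 0")

    @classmethod
    def constant(cls, rate: float, boluses: Sequence[tuple[float, float]] = ()) -> "InfusionProfile":
        return cls((0.0,), (float(rate),), tuple((float(t), float(d)) for t, d in boluses))

    @property
    def bolus_times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.boluses)

    def basal_rate_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.basal_times, t, side="right")) - 1
        return self.basal_rates[max(idx, 0)]

    def total_delivered(self, horizon: float) -> float:
        """Total dose (mU) delivered over [0, horizon]: integral of the
        basal rate plus the boluses falling within the horizon."""
        edges = [t for t in self.basal_times if t < horizon] + [horizon]
        basal = sum(
            self.basal_rates[i] * (edges[i + 1] - edges[i]) for i in range(len(edges) - 1)
        )
        return basal + sum(d for t, d in self.boluses if t <= horizon)

    def to_dict(self) -> dict:
        return {
            "basal_times": list(self.basal_times),
            "basal_rates": list(self.basal_rates),
            "boluses": [list(b) for b in self.boluses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InfusionProfile":
        return cls(
            tuple(d["basal_times"]),
            tuple(d["basal_rates"]),
            tuple((t, dose) for t, dose in d["boluses"]),
        )


@dataclass(frozen=True)
class GlucoseProfile:
    """Evaluable exogenous plasma glucose trace G(t) (mg/dL), needed only by
    hepatic-extraction variant B.  ``G(0) = Gb`` and the trace stays above
    the physiological floor of 40 mg/dL."""

    Gb: float
    _fun: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, t):
        if self._fun is None:
            return self.Gb if np.isscalar(t) else np.full_like(np.asarray(t, float), self.Gb)
        return self._fun(t)

    def validate(self, horizon: float, n_check: int = 289) -> None:
        tt = np.linspace(0.0, horizon, n_check)
        g = np.asarray(self(tt), float)
        if g.min() < 40.0:
            raise ValueError("glucose trace drops below 40 mg/dL")
        if abs(float(self(0.0)) - self.Gb) > 1e-9:
            raise ValueError("G(0) must equal Gb")


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Trajectories on the requested output grid.

    ``states`` has columns (Qip1, Qip2, Qp, Ql) in mU; ``Ip = Qp/VI`` in
    mU/L; ``RaI`` in mU/min; ``HE`` dimensionless.  At a bolus instant the
    reported state is the post-bolus (right-limit) value; Ip itself is
    continuous across boluses.
    """

    times: np.ndarray
    states: np.ndarray
    Ip: np.ndarray
    RaI: np.ndarray
    HE: np.ndarray
    spec: ModelSpec
    clamp_active: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "Qip1": self.states[:, 0],
                "Qip2": self.states[:, 1],
                "Qp": self.states[:, 2],
                "Ql": self.states[:, 3],
                "Ip_mU_per_L": self.Ip,
                "RaI_mU_per_min": self.RaI,
                "HE": self.HE,
            }
        )


def _absorption_flux(variant: AbsorptionVariant, p: AbsorptionParams, q1, q2):
    if variant is AbsorptionVariant.M1:
        return p.ka1 * q1
    if variant is AbsorptionVariant.M2:
        return p.ka2 * q2
    return p.ka1 * q1 + p.ka2 * q2


def _make_rhs(
    variant: AbsorptionVariant,
    he_variant: HEVariant,
    p: AbsorptionParams,
    kin: KineticsParams,
    inf_rate: float,
    glucose: GlucoseProfile | None,
    qlb: float,
    clamp: tuple[float, float],
    m4: float,
):
    """Right-hand side for one constant-input segment (scalar math: the
    solver calls this thousands of times per fit)."""
    m1, m2 = kin.m1, kin.m2
    lo, hi = clamp
    heb, a_g, a_i = kin.HEb, kin.aG, kin.aI
    gb = kin.Gb

    if variant is AbsorptionVariant.M1:
        ka1 = p.ka1

        def ip_part(q1, q2):
            return -ka1 * q1 + inf_rate, 0.0, ka1 * q1

    elif variant is AbsorptionVariant.M2:
        kd, ka2 = p.kd, p.ka2

        def ip_part(q1, q2):
            return -kd * q1 + inf_rate, kd * q1 - ka2 * q2, ka2 * q2

    else:
        ka1, ka2 = p.ka1, p.ka2

        def ip_part(q1, q2):
            return (
                -(ka1 + ka2) * q1 + inf_rate,
                ka2 * (q1 - q2),
                ka1 * q1 + ka2 * q2,
            )

    if he_variant is HEVariant.A:
        he_of = lambda t, ql: heb
    elif he_variant is HEVariant.B:
        he_of = lambda t, ql: -a_g * (glucose(t) - gb) + heb
    else:
        he_of = lambda t, ql: -a_i * (ql - qlb) + heb

    def rhs(t, y):
        q1, q2, qp, ql = y
        dq1, dq2, ra = ip_part(q1, q2)
        he = he_of(t, ql)
        if he < lo:
            he = lo
        elif he > hi:
            he = hi
        m3 = he / (1.0 - he) * m1
        dqp = -(m2 + m4) * qp + m1 * ql
        dql = -(m1 + m3) * ql + m2 * qp + ra
        return (dq1, dq2, dqp, dql)

    return rhs


def _as_param_list(
    absorption: AbsorptionParams | Sequence[AbsorptionParams],
) -> list[AbsorptionParams]:
    if isinstance(absorption, AbsorptionParams):
        return [absorption]
    return list(absorption)


def simulate(
    spec: ModelSpec,
    absorption: AbsorptionParams | Sequence[AbsorptionParams],
    kin: KineticsParams,
    infusion: InfusionProfile,
    glucose: GlucoseProfile | None = None,
    horizon: float = 1440.0,
    t_eval: np.ndarray | None = None,
    *,
    switch_times: Sequence[float] | None = None,
    initial_state: np.ndarray | None = None,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    he_clamp: tuple[float, float] = HE_CLAMP_DEFAULT,
    bolus_duration: float | None = None,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate one model variant over [0, horizon].

    ``absorption`` may be a single parameter set or one per meal period;
    periods are delimited by ``switch_times`` (default: the bolus times
    after the first, so the first set governs the pre-breakfast segment and
    the breakfast bolus, the second takes over at the lunch bolus, etc.).

    Boluses are impulsive additions to Qip1 with an integrator restart;
    setting ``bolus_duration`` (min) instead spreads each bolus as a square
    wave of rate dose/duration.  The initial state defaults to the exact
    basal steady state at the profile's t=0 rate, computed with the first
    period's absorption parameters.
    """
    params = _as_param_list(absorption)
    for p in params:
        p.validate(spec.absorption)
    if spec.hepatic is HEVariant.B:
        if glucose is None:
            raise ValueError("hepatic-extraction variant B requires a glucose profile")
        if kin.Gb is None:
            raise ValueError("variant B requires basal glucose Gb in KineticsParams")
        glucose.validate(horizon)

    if switch_times is None:
        if len(params) > 1:
            bt = sorted(infusion.bolus_times)
            if len(bt) != len(params):
                raise ValueError(
                    f"{len(params)} absorption sets but {len(bt)} boluses: "
                    "pass switch_times explicitly"
                )
            switch_times = bt[1:]
        else:
            switch_times = []
    switch_times = [float(t) for t in switch_times]
    if len(switch_times) != len(params) - 1:
        raise ValueError("need exactly one switch time between consecutive parameter sets")

    m4 = derive_m4(kin)
    inf_b0 = infusion.basal_rate_at(0.0)
    if initial_state is None:
        y = basal_steady_state(spec, params[0], kin, inf_b0)
    else:
        y = np.asarray(initial_state, float).copy()
    qlb = float(y[3])

    if t_eval is None:
        t_eval = np.arange(0.0, horizon + 1e-9, 5.0)
    grid = np.asarray(t_eval, float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if grid[0] < 0 or grid[-1] > horizon + 1e-9:
        raise ValueError("t_eval must lie within [0, horizon]")

    # assemble segment breakpoints: boluses, basal breakpoints, param switches
    impulses: dict[float, float] = {}
    square_sources: list[tuple[float, float, float]] = []  # (t0, t1, rate)
    cuts = {0.0, float(horizon)}
    for t, d in infusion.boluses:
        if t >= horizon:
            raise ValueError(f"bolus at t={t} outside horizon {horizon}")
        if bolus_duration is None:
            impulses[t] = impulses.get(t, 0.0) + d
            cuts.add(float(t))
        else:
            t1 = min(t + bolus_duration, horizon)
            square_sources.append((t, t1, d / bolus_duration))
            cuts.update((float(t), float(t1)))
    cuts.update(t for t in infusion.basal_times if 0.0 < t < horizon)
    cuts.update(t for t in switch_times if 0.0 < t < horizon)
    edges = sorted(cuts)

    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    out_period: list[int] = []
    clamp_hit = False

    for i in range(len(edges) - 1):
        t0, t1 = edges[i], edges[i + 1]
        if t0 in impulses:
            y = y.copy()
            y[0] += impulses[t0]
        period = int(np.searchsorted(switch_times, t0, side="right"))
        p = params[period]
        rate = infusion.basal_rate_at(t0) + sum(
            r for (a, b, r) in square_sources if a <= t0 < b
        )
        rhs = _make_rhs(spec.absorption, spec.hepatic, p, kin, rate, glucose, qlb, he_clamp, m4)

        last = i == len(edges) - 2
        lo_idx = int(np.searchsorted(grid, t0, side="left"))
        hi_idx = int(np.searchsorted(grid, t1, side="right" if last else "left"))
        seg_pts = list(grid[lo_idx:hi_idx])

        if seg_pts and abs(seg_pts[0] - t0) < 1e-12:
            # grid point at the segment start: report the (post-bolus) state
            out_t.append(t0)
            out_y.append(y.copy())
            out_period.append(period)
            seg_pts = seg_pts[1:]
        endpoint_on_grid = bool(seg_pts) and abs(seg_pts[-1] - t1) < 1e-12
        eval_pts = seg_pts if endpoint_on_grid else seg_pts + [t1]
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=eval_pts, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        for k in range(len(seg_pts)):
            out_t.append(float(sol.t[k]))
            out_y.append(sol.y[:, k])
            out_period.append(period)
        y = sol.y[:, -1].copy()

    times = np.array(out_t)
    states = np.vstack(out_y)
    if states[:, :].min() < -1e-9 * max(1.0, states.max()):
        raise SimulationError("state went negative beyond numerical slack")
    periods = np.array(out_period)

    ip = states[:, 2] / kin.VI
    rai = np.empty_like(times)
    for j, p in enumerate(params):
        mask = periods == j
        rai[mask] = _absorption_flux(spec.absorption, p, states[mask, 0], states[mask, 1])

    if spec.hepatic is HEVariant.A:
        he = np.full_like(times, kin.HEb)
    elif spec.hepatic is HEVariant.B:
        raw = -kin.aG * (np.asarray(glucose(times), float) - kin.Gb) + kin.HEb
        clamp_hit = bool(np.any(raw < he_clamp[0]) or np.any(raw > he_clamp[1]))
        he = np.clip(raw, *he_clamp)
    else:
        raw = -kin.aI * (states[:, 3] - qlb) + kin.HEb
        clamp_hit = bool(np.any(raw < he_clamp[0]) or np.any(raw > he_clamp[1]))
        he = np.clip(raw, *he_clamp)
    if clamp_hit:
        logger.warning("hepatic extraction clamped to [%g, %g] during simulation", *he_clamp)

    return SimulationResult(times, states, ip, rai, he, spec, clamp_hit)


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------


def params_to_dict(
    spec: ModelSpec,
    absorption: AbsorptionParams | Sequence[AbsorptionParams],
    kin: KineticsParams,
) -> dict:
    plist = _as_param_list(absorption)
    return {
        "model": str(spec),
        "absorption": [
            {k: v for k, v in vars(p).items() if v is not None} for p in plist
        ],
        "kinetics": {k: v for k, v in vars(kin).items() if v is not None},
    }


def params_from_dict(d: dict) -> tuple[ModelSpec, list[AbsorptionParams], KineticsParams]:
    spec = ModelSpec.from_string(d["model"])
    plist = [AbsorptionParams(**p) for p in d["absorption"]]
    kin = KineticsParams(**d["kinetics"])
    return spec, plist, kin


def params_to_json(spec, absorption, kin) -> str:
    return json.dumps(params_to_dict(spec, absorption, kin), indent=2)


def params_from_json(s: str):
    return params_from_dict(json.loads(s))
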