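"""Bayesian Maximum a Posteriori identification of the IP insulin models.

The objective is weighted least squares on plasma insulin (Gaussian
measurement error of known SD) plus log-normal prior penalties on the
whole-body kinetics parameters VI, m1, CL and HEb; IP absorption parameters
and the hepatic-extraction controls aG/aI carry flat positivity-constrained
priors.  The search runs in transformed coordinates: logs for positive
rates and volumes, a logit for HEb, kd = ka2*(1+delta) with delta >= 0 to
enforce the kd >= ka2 convention, and the peripheral degradation rate m4
(log) as the free coordinate behind the derived clearance
CL = (HEb*m2 + m4)*VI, which keeps m4 >= 0 by construction.

Post-fit, two structural simplification rules are applied and the reduced
model refitted: in M2, kd is collapsed onto ka2 when their relative
difference is below 1%; in M3, ka1 is collapsed to zero when it falls
below 1e-3 min^-1.

Precision comes from a Gauss-Newton approximation of the posterior
information matrix (residual Jacobian by central finite differences,
optionally including the prior curvature), mapped to per-parameter CVs by
the delta method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .pk_models import (
    HE_CLAMP_DEFAULT,
    M2_DEFAULT,
    AbsorptionParams,
    AbsorptionVariant,
    DegenerateParametersError,
    HEVariant,
    KineticsParams,
    ModelSpec,
    SimulationError,
    simulate,
)
from .synthetic_data import InsulinDataset

logger = logging.getLogger("ipinsulin")

__all__ = [
    "PriorSpec",
    "FitConfig",
    "FitResult",
    "negative_log_posterior",
    "fit_map",
    "weighted_residuals",
    "parameter_cv",
    "information_cvs",
]

_PENALTY = 1e4  # residual fill-in when the simulator fails mid-search


def sigma_ln(cv: float) -> float:
    """Log-scale SD of a log-normal with the given coefficient of variation."""
    if cv <= 0:
        raise ValueError("prior CV must be > 0")
    return math.sqrt(math.log(1.0 + cv * cv))


@dataclass(frozen=True)
class PriorSpec:
    """Log-normal priors keyed by parameter name (median, CV); parameters
    not listed get flat positivity-constrained priors.  By default only the
    whole-body kinetics parameters VI, m1, CL and HEb are informed."""

    lognormal: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (med, cv) in self.lognormal.items():
            if med <= 0 or cv <= 0:
                raise ValueError(f"prior on {name} needs positive median and CV")
            if name == "HEb" and med >= 1.0:
                raise ValueError("prior median for HEb must be < 1")

    @classmethod
    def for_kinetics(
        cls, VI: float, m1: float, CL: float, HEb: float, cv: float = 1.0
    ) -> "PriorSpec":
        return cls({"VI": (VI, cv), "m1": (m1, cv), "CL": (CL, cv), "HEb": (HEb, cv)})

    def scaled(self, factor: float) -> "PriorSpec":
        """Same priors with all medians multiplied by ``factor`` (used to
        de-center priors away from a known truth)."""
        return PriorSpec({k: (m * factor, cv) for k, (m, cv) in self.lognormal.items()})

    def residuals(self, natural: dict[str, float]) -> list[float]:
        out = []
        for name, (med, cv) in self.lognormal.items():
            theta = natural[name]
            if theta <= 0:
                return [1e6] * len(self.lognormal)
            out.append((math.log(theta) - math.log(med)) / sigma_ln(cv))
        return out

    def penalty(self, natural: dict[str, float]) -> float:
        return 0.5 * sum(r * r for r in self.residuals(natural))


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the MAP fit; defaults follow the identification protocol."""

    m2: float = M2_DEFAULT
    kd_collapse_rel: float = 0.01   # rule (i): collapse kd onto ka2 below this relative gap
    ka1_floor: float = 1e-3        # rule (ii): collapse ka1 to 0 below this (min^-1)
    restarts: int = 5
    jitter_sd: float = 0.3          # log-space SD of multi-start jitter
    seed: int = 0
    meal_varying: bool = True
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-8
    ftol: float = 1e-10
    xtol: float = 1e-10
    diff_step: float = 1e-4  # optimizer FD step; must dominate solver noise at sim_rtol
    max_nfev: int | None = None
    he_clamp: tuple[float, float] = HE_CLAMP_DEFAULT
    include_prior_in_fim: bool = True
    fd_rel_step: float = 1e-4
    fixed: dict = field(default_factory=dict)   # natural name -> value, held out of the fit
    init: dict = field(default_factory=dict)    # natural name -> start value override


# ---------------------------------------------------------------------------
# Transformed coordinates
# ---------------------------------------------------------------------------


@dataclass
class _Coord:
    name: str      # internal natural name ("ka1_m2", "VI", "m4", "delta_m1", "aI")
    report: str    # reported name ("ka1_m2", "VI", "CL", "kd_m1", "aI")
    kind: str      # "log" | "logit" | "linear"
    scale: float = 1.0
    lb: float = -np.inf
    ub: float = np.inf

    def to_x(self, natural: float) -> float:
        if self.kind == "log":
            return math.log(max(natural, 1e-12))
        if self.kind == "logit":
            v = min(max(natural, 1e-9), 1 - 1e-9)
            return math.log(v / (1 - v))
        return natural / self.scale

    def to_natural(self, x: float) -> float:
        if self.kind == "log":
            return math.exp(x)
        if self.kind == "logit":
            return 1.0 / (1.0 + math.exp(-x))
        return x * self.scale


class _Problem:
    """Mutable fit problem: coordinate list, residuals, simplification."""

    def __init__(
        self,
        spec: ModelSpec,
        dataset: InsulinDataset,
        priors: PriorSpec,
        config: FitConfig,
    ):
        self.spec = spec
        self.dataset = dataset
        self.priors = priors
        self.config = config
        self.collapsed: dict[str, str] = {}
        self.nfev = 0

        if spec.hepatic is HEVariant.B and dataset.glucose_profile is None:
            raise ValueError("hepatic-extraction variant B requires glucose in the dataset")
        self.Gb = dataset.glucose_profile.Gb if dataset.glucose_profile is not None else None

        n_meals = len(dataset.meal_times) if config.meal_varying else 1
        self.n_meals = n_meals
        self.switch_times = list(dataset.meal_times[1:]) if config.meal_varying else []

        fixed = dict(config.fixed)
        # fixing CL (given fixed VI and HEb) is equivalent to fixing m4
        if "CL" in fixed:
            if not ("VI" in fixed and "HEb" in fixed):
                raise ValueError("fixing CL requires fixing VI and HEb as well")
            fixed["m4"] = fixed["CL"] / fixed["VI"] - fixed["HEb"] * config.m2
        self.fixed = fixed

        self.coords: list[_Coord] = []
        init = self._default_inits()
        init.update(config.init)
        self._init_natural = init

        def add(name, report, kind, scale=1.0, lb=-np.inf, ub=np.inf):
            base = name.split("_m")[0]
            if name in fixed or base in fixed:
                return
            self.coords.append(_Coord(name, report, kind, scale, lb, ub))

        for i in range(1, n_meals + 1):
            sfx = f"_m{i}" if config.meal_varying else ""
            if spec.absorption is AbsorptionVariant.M1:
                add(f"ka1{sfx}", f"ka1{sfx}", "log")
            elif spec.absorption is AbsorptionVariant.M2:
                add(f"ka2{sfx}", f"ka2{sfx}", "log")
                add(f"delta{sfx}", f"kd{sfx}", "linear", 1.0, 0.0, np.inf)
            else:
                add(f"ka1{sfx}", f"ka1{sfx}", "log", lb=math.log(1e-8))
                add(f"ka2{sfx}", f"ka2{sfx}", "log")
        add("VI", "VI", "log")
        add("m1", "m1", "log")
        add("m4", "CL", "log")
        add("HEb", "HEb", "logit")
        if spec.hepatic is HEVariant.B:
            add("aG", "aG", "linear", 1e-3, 0.0, np.inf)
        elif spec.hepatic is HEVariant.C:
            add("aI", "aI", "linear", 1e-4, 0.0, np.inf)

    # -- inits ---------------------------------------------------------------

    def _default_inits(self) -> dict[str, float]:
        pri = self.priors.lognormal
        vi = pri.get("VI", (4.0,))[0]
        m1 = pri.get("m1", (0.2,))[0]
        heb = pri.get("HEb", (0.6,))[0]
        cl = pri.get("CL", (1.2,))[0]
        m4 = cl / vi - heb * self.config.m2
        if m4 <= 0:
            m4 = 0.05
        init = {"VI": vi, "m1": m1, "HEb": heb, "m4": m4, "aG": 2e-4, "aI": 5e-5}
        for i in range(1, self.n_meals + 1):
            sfx = f"_m{i}" if self.config.meal_varying else ""
            init[f"ka1{sfx}"] = 0.01
            init[f"ka2{sfx}"] = 0.02
            init[f"delta{sfx}"] = 0.5
        return init

    def x0(self) -> np.ndarray:
        vals = []
        for c in self.coords:
            base = c.name.split("_m")[0]
            nat = self._init_natural.get(c.name, self._init_natural.get(base))
            vals.append(c.to_x(nat))
        return np.array(vals)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([c.lb for c in self.coords]),
            np.array([c.ub for c in self.coords]),
        )

    def x_from_natural(self, natural: dict[str, float]) -> np.ndarray:
        return np.array([c.to_x(natural[c.name]) for c in self.coords])

    # -- natural-space assembly ----------------------------------------------

    def natural(self, x: np.ndarray) -> dict[str, float]:
        nat = {c.name: c.to_natural(xi) for c, xi in zip(self.coords, x)}
        for name, v in self.fixed.items():
            nat.setdefault(name, v)
        # broadcast base-name fixing to meal slots
        for i in range(1, self.n_meals + 1):
            sfx = f"_m{i}" if self.config.meal_varying else ""
            for base in ("ka1", "ka2", "delta"):
                key = f"{base}{sfx}"
                if key not in nat and base in self.fixed:
                    nat[key] = self.fixed[base]
        for name, why in self.collapsed.items():
            nat[name] = 0.0
        return nat

    def assemble(self, nat: dict[str, float]):
        cfg = self.config
        absorption = []
        for i in range(1, self.n_meals + 1):
            sfx = f"_m{i}" if cfg.meal_varying else ""
            if self.spec.absorption is AbsorptionVariant.M1:
                absorption.append(AbsorptionParams(ka1=nat[f"ka1{sfx}"]))
            elif self.spec.absorption is AbsorptionVariant.M2:
                ka2 = nat[f"ka2{sfx}"]
                kd = ka2 * (1.0 + nat[f"delta{sfx}"])
                absorption.append(AbsorptionParams(ka2=ka2, kd=kd))
            else:
                absorption.append(
                    AbsorptionParams(ka1=nat[f"ka1{sfx}"], ka2=nat[f"ka2{sfx}"])
                )
        cl = (nat["HEb"] * cfg.m2 + nat["m4"]) * nat["VI"]
        kin = KineticsParams(
            VI=nat["VI"],
            m1=nat["m1"],
            CL=cl,
            HEb=nat["HEb"],
            m2=cfg.m2,
            aG=nat.get("aG", 0.0),
            aI=nat.get("aI", 0.0),
            Gb=self.Gb,
        )
        return absorption, kin

    def reported(self, nat: dict[str, float]) -> dict[str, float]:
        """Natural estimates in the field's reporting convention (CL rather
        than m4, kd rather than delta)."""
        out = {}
        for i in range(1, self.n_meals + 1):
            sfx = f"_m{i}" if self.config.meal_varying else ""
            if self.spec.absorption is AbsorptionVariant.M1:
                out[f"ka1{sfx}"] = nat[f"ka1{sfx}"]
            elif self.spec.absorption is AbsorptionVariant.M2:
                out[f"ka2{sfx}"] = nat[f"ka2{sfx}"]
                out[f"kd{sfx}"] = nat[f"ka2{sfx}"] * (1.0 + nat[f"delta{sfx}"])
            else:
                out[f"ka1{sfx}"] = nat[f"ka1{sfx}"]
                out[f"ka2{sfx}"] = nat[f"ka2{sfx}"]
        out["VI"] = nat["VI"]
        out["m1"] = nat["m1"]
        out["HEb"] = nat["HEb"]
        out["m4"] = nat["m4"]
        out["CL"] = (nat["HEb"] * self.config.m2 + nat["m4"]) * nat["VI"]
        if self.spec.hepatic is HEVariant.B:
            out["aG"] = nat.get("aG", 0.0)
        elif self.spec.hepatic is HEVariant.C:
            out["aI"] = nat.get("aI", 0.0)
        return out

    # -- residuals -------------------------------------------------------------

    def predict(self, nat: dict[str, float]) -> np.ndarray:
        absorption, kin = self.assemble(nat)
        res = simulate(
            self.spec,
            absorption,
            kin,
            self.dataset.infusion,
            glucose=self.dataset.glucose_profile,
            horizon=self.dataset.horizon,
            t_eval=self.dataset.times,
            switch_times=self.switch_times,
            rtol=self.config.sim_rtol,
            atol=self.config.sim_atol,
            he_clamp=self.config.he_clamp,
        )
        return res.Ip

    def residuals(self, x: np.ndarray) -> np.ndarray:
        self.nfev += 1
        nat = self.natural(x)
        n_res = self.dataset.n + len(self.priors.lognormal)
        try:
            pred = self.predict(nat)
        except (SimulationError, DegenerateParametersError, ValueError) as exc:
            logger.warning("simulation failed during fit (%s); penalizing", exc)
            return np.full(n_res, _PENALTY)
        r_data = (self.dataset.insulin - pred) / self.dataset.sd
        rep = self.reported(nat)
        r_prior = self.priors.residuals(rep)
        return np.concatenate([r_data, r_prior])

    # -- simplification ---------------------------------------------------------

    def simplification_triggers(self, nat: dict[str, float]) -> dict[str, str]:
        cfg = self.config
        trig: dict[str, str] = {}
        for c in self.coords:
            base = c.name.split("_m")[0]
            if self.spec.absorption is AbsorptionVariant.M2 and base == "delta":
                if nat[c.name] < cfg.kd_collapse_rel:
                    trig[c.name] = "kd collapsed onto ka2 (relative difference < 1%)"
            if self.spec.absorption is AbsorptionVariant.M3 and base == "ka1":
                if nat[c.name] < cfg.ka1_floor:
                    trig[c.name] = "ka1 collapsed to 0 (below 1e-3 min^-1)"
        return trig

    def collapse(self, names: dict[str, str], x: np.ndarray) -> np.ndarray:
        keep = [i for i, c in enumerate(self.coords) if c.name not in names]
        self.collapsed.update(names)
        self.coords = [self.coords[i] for i in keep]
        return x[keep]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def weighted_residuals(dataset: InsulinDataset, prediction: np.ndarray) -> np.ndarray:
    """Elementwise (data - prediction)/SD."""
    prediction = np.asarray(prediction, float)
    if prediction.shape != dataset.insulin.shape:
        raise ValueError("prediction and data lengths differ")
    if np.any(dataset.sd == 0):
        raise ValueError("zero SD")
    return (dataset.insulin - prediction) / dataset.sd


def negative_log_posterior(
    theta: dict[str, float],
    spec: ModelSpec,
    dataset: InsulinDataset,
    priors: PriorSpec,
    config: FitConfig | None = None,
) -> float:
    """0.5 * WRSS(theta) + log-normal prior penalties.

    ``theta`` is a complete natural-space parameter dict (per-meal
    absorption entries, VI, m1, HEb and either CL or m4, plus aG/aI when
    the variant needs them).
    """
    config = config or FitConfig()
    problem = _Problem(spec, dataset, priors, config)
    theta = dict(theta)
    if "m4" not in theta:
        if "CL" not in theta:
            raise ValueError("theta needs CL or m4")
        theta["m4"] = theta["CL"] / theta["VI"] - theta["HEb"] * config.m2
        if theta["m4"] < 0:
            raise DegenerateParametersError("CL/VI <= HEb*m2")
    full = {**problem._init_natural, **theta}
    pred = problem.predict(full)
    wrss = float(np.sum(((dataset.insulin - pred) / dataset.sd) ** 2))
    return 0.5 * wrss + priors.penalty(problem.reported(full))


@dataclass
class FitResult:
    """MAP estimates, precision, residuals and simplification flags."""

    spec: ModelSpec
    estimates: dict[str, float]          # reported natural-space values
    free_names: list[str]                # reported names of free parameters
    cov_x: np.ndarray                    # covariance in transformed space
    cv: dict[str, float]                 # CV% per reported parameter
    wrss: float
    residuals: np.ndarray                # weighted residual series, length N
    predictions: np.ndarray
    collapsed: dict[str, str]            # reported name -> rule description
    n_free: int                          # P after simplification
    n_obs: int
    objective: float
    converged: bool
    n_starts: int
    message: str = ""
    nfev: int = 0
    cv_includes_prior: bool = True
    absorption: list[AbsorptionParams] = field(default_factory=list)
    kinetics: KineticsParams | None = None

    def to_json_dict(self) -> dict:
        return {
            "model": str(self.spec),
            "estimates": self.estimates,
            "cv_percent": self.cv,
            "wrss": self.wrss,
            "n_free": self.n_free,
            "n_obs": self.n_obs,
            "collapsed": self.collapsed,
            "objective": self.objective,
            "converged": self.converged,
            "cv_includes_prior": self.cv_includes_prior,
        }


def parameter_cv(fit: FitResult) -> dict[str, float]:
    """CV% per estimated parameter, 100*sqrt(Var)/|estimate|; collapsed
    parameters carry no CV; a singular information matrix yields inf."""
    return dict(fit.cv)


def _cv_from_cov(problem: _Problem, x: np.ndarray, cov_x: np.ndarray) -> dict[str, float]:
    """Delta-method CVs of the reported parameters from the transformed-space
    covariance: CV = 100*sqrt(g' C g)/|theta| with g the numeric gradient of
    each reported parameter w.r.t. the transformed coordinates."""
    nat = problem.natural(x)
    rep0 = problem.reported(nat)
    names = [c.report for c in problem.coords]
    # kd is reported alongside ka2 for M2; CL alongside m4 — the mapping from
    # coords to reported names is 1:1 via _Coord.report, but kd and CL depend
    # on several coordinates, hence the full gradient.
    grads = {}
    h = 1e-6
    base = {n: rep0[n] for n in rep0}
    for j in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        rp = problem.reported(problem.natural(xp))
        rm = problem.reported(problem.natural(xm))
        for n in rep0:
            grads.setdefault(n, np.zeros(len(x)))[j] = (rp[n] - rm[n]) / (2 * h)
    cvs = {}
    for n in names:
        g = grads[n]
        var = float(g @ cov_x @ g)
        theta = base[n]
        if var < 0 or not np.isfinite(var) or theta == 0:
            cvs[n] = float("inf")
        else:
            cvs[n] = 100.0 * math.sqrt(var) / abs(theta)
    # CL is derived whenever m4 is free; attach its CV alongside
    if "CL" in grads and "CL" not in cvs and any(c.name == "m4" for c in problem.coords):
        g = grads["CL"]
        cvs["CL"] = 100.0 * math.sqrt(max(float(g @ cov_x @ g), 0.0)) / abs(base["CL"])
    return cvs


def _fd_jacobian(problem: _Problem, x: np.ndarray, include_prior: bool) -> np.ndarray:
    """Central-difference Jacobian of the residual vector (data rows, plus
    prior rows when the posterior information is requested)."""
    r0 = problem.residuals(x)
    n_data = problem.dataset.n
    rows = len(r0) if include_prior else n_data
    J = np.zeros((rows, len(x)))
    for j in range(len(x)):
        h = problem.config.fd_rel_step * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        rp = problem.residuals(xp)[:rows]
        rm = problem.residuals(xm)[:rows]
        J[:, j] = (rp - rm) / (2 * h)
    return J


def _covariance(J: np.ndarray) -> np.ndarray:
    info = J.T @ J
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        return cov
    except np.linalg.LinAlgError:
        return np.full_like(info, np.inf)


def fit_map(
    spec: ModelSpec,
    dataset: InsulinDataset,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """MAP fit of one model variant to one subject's dataset.

    Multi-start trust-region least squares on the stacked (weighted data
    residual, prior residual) vector in transformed coordinates; the best
    start wins.  Simplification rules are then applied and the reduced
    model refitted until no rule triggers.
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    problem = _Problem(spec, dataset, priors, config)
    rng = np.random.default_rng(config.seed)

    x0 = problem.x0()
    lo, hi = problem.bounds()
    starts = [x0]
    for _ in range(max(config.restarts - 1, 0)):
        jitter = rng.normal(0.0, config.jitter_sd, size=x0.shape)
        starts.append(np.clip(x0 + jitter, lo, hi + 0.0))

    def solve(x_start):
        return least_squares(
            problem.residuals,
            np.clip(x_start, lo, hi),
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            diff_step=config.diff_step,
            max_nfev=config.max_nfev,
        )

    best = None
    for x_s in starts:
        sol = solve(x_s)
        if best is None or sol.cost < best.cost:
            best = sol

    # The M2 objective is quartically flat in kd - ka2 near equality, so
    # gradient steps stall at a small spurious gap; a boundary start with
    # every delta at 0 finds the collapsed optimum when it is the true one.
    delta_idx = [i for i, c in enumerate(problem.coords) if c.name.startswith("delta")]
    if delta_idx:
        x_b = best.x.copy()
        x_b[delta_idx] = 0.0
        sol = solve(x_b)
        if sol.cost < best.cost:
            best = sol

    # structural simplification, refit until stable
    for _ in range(3):
        nat = problem.natural(best.x)
        trig = problem.simplification_triggers(nat)
        if not trig:
            break
        logger.info("simplification triggered: %s", trig)
        x_red = problem.collapse(trig, best.x)
        lo, hi = problem.bounds()
        best = solve(x_red)

    nat = problem.natural(best.x)
    estimates = problem.reported(nat)
    absorption_fit, kinetics_fit = problem.assemble(nat)
    pred = problem.predict(nat)
    res = weighted_residuals(dataset, pred)
    wrss = float(np.sum(res**2))

    J = _fd_jacobian(problem, best.x, config.include_prior_in_fim)
    cov_x = _covariance(J)
    if np.all(np.isfinite(cov_x)):
        cvs = _cv_from_cov(problem, best.x, cov_x)
    else:
        cvs = {c.report: float("inf") for c in problem.coords}

    collapsed_reported = {}
    for name, why in problem.collapsed.items():
        rep = name.replace("delta", "kd") if name.startswith("delta") else name
        collapsed_reported[rep] = why

    return FitResult(
        spec=spec,
        estimates=estimates,
        free_names=[c.report for c in problem.coords],
        cov_x=cov_x,
        cv=cvs,
        wrss=wrss,
        residuals=res,
        predictions=pred,
        collapsed=collapsed_reported,
        n_free=len(problem.coords),
        n_obs=dataset.n,
        objective=float(best.cost),
        converged=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
        nfev=problem.nfev,
        cv_includes_prior=config.include_prior_in_fim,
        absorption=absorption_fit,
        kinetics=kinetics_fit,
    )


def information_cvs(
    spec: ModelSpec,
    dataset: InsulinDataset,
    natural: dict[str, float],
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
) -> dict[str, float]:
    """Expected CVs at a given parameter point, without fitting: the
    Gauss-Newton information evaluated at ``natural`` (same keys as
    ``negative_log_posterior``).  Useful for design questions such as the
    effect of sampling density on attainable precision."""
    priors = priors or PriorSpec()
    config = config or FitConfig()
    problem = _Problem(spec, dataset, priors, config)
    natural = dict(natural)
    if "m4" not in natural:
        natural["m4"] = natural["CL"] / natural["VI"] - natural["HEb"] * config.m2
    x = problem.x_from_natural(natural)
    J = _fd_jacobian(problem, x, config.include_prior_in_fim)
    cov_x = _covariance(J)
    if not np.all(np.isfinite(cov_x)):
        return {c.report: float("inf") for c in problem.coords}
    return _cv_from_cov(problem, x, cov_x)
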