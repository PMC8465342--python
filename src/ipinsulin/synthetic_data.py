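"""Virtual-subject generation emulating a hospitalized 24-h open-loop study
day with intraperitoneal basal-bolus insulin delivery.

The generator reproduces the statistical structure the identification
machinery assumes: a piecewise-constant basal rate plus three meal boluses,
frequent plasma-insulin sampling with uncorrelated zero-mean Gaussian
measurement error of known standard deviation, and (optionally) meal-by-meal
variability of the IP absorption parameters.  True parameters are stored
alongside each dataset so recovery experiments can score themselves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_models import (
    MILLIUNITS_PER_UNIT,
    AbsorptionParams,
    DegenerateParametersError,
    GlucoseProfile,
    InfusionProfile,
    KineticsParams,
    ModelSpec,
    params_to_dict,
    simulate,
)

__all__ = [
    "InfusionProfile",
    "GlucoseProfile",
    "InsulinDataset",
    "VirtualSubject",
    "DEFAULT_MEAL_TIMES",
    "build_open_loop_design",
    "build_glucose_profile",
    "measurement_sd",
    "simulate_subject",
    "generate_dataset",
    "sample_population",
]

#: Study day starts at 07:00; breakfast 08:00, lunch 13:00, dinner 19:00.
DEFAULT_MEAL_TIMES = (60.0, 360.0, 720.0)

#: Plasma-insulin assay error model: SD = max(cv * Ip, floor).  Typical of
#: plasma-insulin immunoassays; both knobs are configurable everywhere.
DEFAULT_CV = 0.06
DEFAULT_SD_FLOOR = 1.0  # mU/L


def build_open_loop_design(
    daily_dose: float,
    body_mass: float,
    meal_times: Sequence[float] = DEFAULT_MEAL_TIMES,
    bolus_fraction: float = 0.5,
    bolus_split: Sequence[float] | None = None,
    horizon: float = 1440.0,
) -> InfusionProfile:
    """Basal-bolus IP infusion for one 24-h day.

    ``daily_dose`` is in U/kg/day; ``bolus_fraction`` of the total goes to
    meal boluses (split equally unless ``bolus_split`` gives weights), the
    rest to a constant basal rate.  The delivered total over the horizon
    equals daily_dose * body_mass exactly.
    """
    if daily_dose <= 0 or body_mass <= 0:
        raise ValueError("daily dose and body mass must be positive")
    if not 0.0 <= bolus_fraction < 1.0:
        raise ValueError("bolus_fraction must be in [0, 1)")
    meal_times = [float(t) for t in meal_times]
    if any(not 0.0 <= t < horizon for t in meal_times):
        raise ValueError("meal times must lie in [0, horizon)")

    total_mU = daily_dose * body_mass * MILLIUNITS_PER_UNIT
    basal_rate = (1.0 - bolus_fraction) * total_mU / horizon
    bolus_total = bolus_fraction * total_mU
    if bolus_fraction == 0.0 or not meal_times:
        return InfusionProfile.constant(basal_rate)
    if bolus_split is None:
        weights = np.full(len(meal_times), 1.0 / len(meal_times))
    else:
        weights = np.asarray(bolus_split, float)
        weights = weights / weights.sum()
    boluses = [(t, bolus_total * w) for t, w in zip(meal_times, weights)]
    return InfusionProfile.constant(basal_rate, boluses)


def build_glucose_profile(
    Gb: float = 120.0,
    meal_times: Sequence[float] = DEFAULT_MEAL_TIMES,
    excursion_amplitudes: Sequence[float] | float = 60.0,
    peak_delay: float = 60.0,
    width: float = 0.5,
    amplitude_jitter: float = 0.0,
    seed: int | None = None,
) -> GlucoseProfile:
    """Basal glucose plus one smooth postprandial excursion per meal.

    Each excursion is a log-normal-shaped bump peaking ``peak_delay`` min
    after the meal with peak height equal to its amplitude (mg/dL);
    ``width`` is the log-scale shape parameter.  With ``amplitude_jitter``
    > 0 the amplitudes are perturbed multiplicatively (log-normal, seeded),
    which keeps the trace deterministic for a given seed.
    """
    meal_times = np.asarray(meal_times, float)
    amps = np.broadcast_to(np.asarray(excursion_amplitudes, float), meal_times.shape).copy()
    if np.any(amps < 0):
        raise ValueError("excursion amplitudes must be >= 0")
    if amplitude_jitter > 0:
        rng = np.random.default_rng(seed)
        amps = amps * np.exp(rng.normal(0.0, amplitude_jitter, size=amps.shape))

    def fun(t):
        t = np.asarray(t, float)
        g = np.full(t.shape, Gb)
        for tm, a in zip(meal_times, amps):
            if a == 0:
                continue
            tau = t - tm
            with np.errstate(divide="ignore", invalid="ignore"):
                bump = np.where(
                    tau > 0,
                    np.exp(-np.log(np.where(tau > 0, tau, 1.0) / peak_delay) ** 2 / (2 * width**2)),
                    0.0,
                )
            g = g + a * bump
        return g if g.shape else float(g)

    return GlucoseProfile(Gb=float(Gb), _fun=fun)


def measurement_sd(
    Ip: float | np.ndarray, cv: float = DEFAULT_CV, floor: float = DEFAULT_SD_FLOOR
) -> float | np.ndarray:
    """Known measurement SD of a plasma-insulin sample: max(cv*Ip, floor)."""
    if cv <= 0:
        raise ValueError("cv must be > 0")
    return np.maximum(cv * np.asarray(Ip, float), floor) if not np.isscalar(Ip) else max(cv * Ip, floor)


# ---------------------------------------------------------------------------
# Subjects and datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VirtualSubject:
    """Ground-truth parameter set of one simulated subject."""

    kinetics: KineticsParams
    absorption: tuple[AbsorptionParams, ...]
    basal_rate: float = 0.0  # mU/min; informational, the design carries the rate used
    body_mass: float = 75.0  # kg, dose scaling only


@dataclass
class InsulinDataset:
    """Sampled noisy plasma insulin with per-sample SDs and study inputs.

    ``truth`` is present only for synthetic data (model string, parameters,
    generation settings).  Negative noise draws are truncated at zero and
    flagged in ``truncated``.
    """

    times: np.ndarray
    insulin: np.ndarray
    sd: np.ndarray
    infusion: InfusionProfile
    meal_times: tuple[float, ...]
    horizon: float
    glucose: np.ndarray | None = None
    glucose_profile: GlucoseProfile | None = None
    truth: dict | None = None
    truncated: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.insulin = np.asarray(self.insulin, float)
        self.sd = np.asarray(self.sd, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.sd <= 0):
            raise ValueError("per-sample SDs must be > 0")
        if np.any(self.insulin < 0):
            raise ValueError("measured insulin must be >= 0")

    @property
    def n(self) -> int:
        return len(self.times)

    # -- persistence: tidy CSV + JSON sidecar --------------------------------

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        df = pd.DataFrame(
            {
                "time_min": self.times,
                "insulin_mU_per_L": self.insulin,
                "sd_mU_per_L": self.sd,
                "glucose_mg_per_dL": (
                    self.glucose if self.glucose is not None else np.full(self.n, np.nan)
                ),
            }
        )
        df.to_csv(csv_path, index=False)
        meta = {
            "infusion": self.infusion.to_dict(),
            "meal_times": list(self.meal_times),
            "horizon": self.horizon,
            "truth": self.truth,
            "seed": self.seed,
            "truncated_indices": (
                [int(i) for i in np.flatnonzero(self.truncated)]
                if self.truncated is not None
                else []
            ),
        }
        json_path.write_text(json.dumps(meta, indent=2))
        return csv_path, json_path

    @classmethod
    def from_files(cls, prefix: str | Path) -> "InsulinDataset":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        glucose = df["glucose_mg_per_dL"].to_numpy()
        has_glucose = not np.all(np.isnan(glucose))
        gp = None
        if has_glucose:
            tt, gg = df["time_min"].to_numpy(), glucose
            gp = GlucoseProfile(Gb=float(gg[0]), _fun=lambda t: np.interp(t, tt, gg))
        truncated = np.zeros(len(df), bool)
        truncated[meta.get("truncated_indices", [])] = True
        return cls(
            times=df["time_min"].to_numpy(),
            insulin=df["insulin_mU_per_L"].to_numpy(),
            sd=df["sd_mU_per_L"].to_numpy(),
            infusion=InfusionProfile.from_dict(meta["infusion"]),
            meal_times=tuple(meta["meal_times"]),
            horizon=float(meta["horizon"]),
            glucose=glucose if has_glucose else None,
            glucose_profile=gp,
            truth=meta.get("truth"),
            truncated=truncated,
            seed=meta.get("seed"),
        )


def simulate_subject(
    subject: VirtualSubject,
    spec: ModelSpec,
    design: InfusionProfile,
    glucose: GlucoseProfile | None,
    sample_times: np.ndarray,
    horizon: float = 1440.0,
    **sim_kwargs,
) -> np.ndarray:
    """Noise-free plasma insulin (mU/L) of ``subject`` at ``sample_times``."""
    res = simulate(
        spec,
        list(subject.absorption),
        subject.kinetics,
        design,
        glucose=glucose,
        horizon=horizon,
        t_eval=np.asarray(sample_times, float),
        **sim_kwargs,
    )
    return res.Ip


def generate_dataset(
    subject: VirtualSubject,
    spec: ModelSpec,
    design: InfusionProfile,
    glucose: GlucoseProfile | None = None,
    sampling_interval: float = 10.0,
    horizon: float = 1440.0,
    cv: float = DEFAULT_CV,
    sd_floor: float = DEFAULT_SD_FLOOR,
    seed: int | None = None,
    truth_trace: np.ndarray | None = None,
    sample_times: np.ndarray | None = None,
    **sim_kwargs,
) -> InsulinDataset:
    """One noisy study day: simulate, perturb with Gaussian error of known
    SD = max(cv*Ip, floor), truncate negative draws at zero (flagged).

    ``truth_trace`` short-circuits the forward simulation when the
    noise-free trace at ``sample_times`` is already available (replicated
    noise draws on a fixed subject).  With ``cv=0`` the measurements equal
    the noise-free simulation exactly and the stored SDs fall back to the
    floor (SDs must stay positive for weighting).
    """
    if sample_times is None:
        sample_times = np.arange(0.0, horizon + 1e-9, sampling_interval)
    sample_times = np.asarray(sample_times, float)
    if truth_trace is None:
        truth_trace = simulate_subject(
            subject, spec, design, glucose, sample_times, horizon, **sim_kwargs
        )
    truth_trace = np.asarray(truth_trace, float)

    sd = np.maximum(cv * truth_trace, sd_floor) if cv > 0 else np.full_like(truth_trace, sd_floor)
    rng = np.random.default_rng(seed)
    noisy = truth_trace + (rng.standard_normal(truth_trace.shape) * sd if cv > 0 else 0.0)
    truncated = noisy < 0
    noisy = np.where(truncated, 0.0, noisy)

    meal_times = tuple(design.bolus_times) or tuple(DEFAULT_MEAL_TIMES)
    truth = params_to_dict(spec, list(subject.absorption), subject.kinetics)
    truth.update({"cv": cv, "sd_floor": sd_floor, "body_mass": subject.body_mass})
    return InsulinDataset(
        times=sample_times,
        insulin=noisy,
        sd=sd,
        infusion=design,
        meal_times=meal_times,
        horizon=horizon,
        glucose=np.asarray(glucose(sample_times), float) if glucose is not None else None,
        glucose_profile=glucose,
        truth=truth,
        truncated=truncated,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def sample_population(
    n_subjects: int,
    median_kinetics: KineticsParams,
    median_absorption: Sequence[AbsorptionParams],
    spec: ModelSpec,
    dispersion: float = 0.3,
    meal_variability: float = 0.0,
    basal_rate: float = 15.625,
    body_mass: float = 75.0,
    seed: int | None = None,
    max_retries: int = 200,
) -> list[VirtualSubject]:
    """Log-normal population around the median parameter set.

    Positive parameters get multiplicative log-normal perturbations with
    log-SD ``dispersion`` (so the population median equals the center);
    HEb is perturbed on the logit scale with the same SD.  With
    ``meal_variability`` > 0, ka1/ka2/kd additionally receive independent
    per-meal log-normal factors, emulating between-meal variability of IP
    absorption.  Draws violating feasibility (HEb in (0,1), m4 >= 0,
    kd >= ka2) are redrawn up to ``max_retries`` times.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    kin0 = median_kinetics
    subjects: list[VirtualSubject] = []

    def lognorm(center: float, sd: float) -> float:
        return center * math.exp(rng.normal(0.0, sd)) if sd > 0 and center > 0 else center

    for _ in range(n_subjects):
        for attempt in range(max_retries):
            try:
                heb = kin0.HEb
                if dispersion > 0:
                    logit = math.log(heb / (1 - heb)) + rng.normal(0.0, dispersion)
                    heb = 1.0 / (1.0 + math.exp(-logit))
                kin = KineticsParams(
                    VI=lognorm(kin0.VI, dispersion),
                    m1=lognorm(kin0.m1, dispersion),
                    CL=lognorm(kin0.CL, dispersion),
                    HEb=heb,
                    m2=kin0.m2,
                    aG=lognorm(kin0.aG, dispersion),
                    aI=lognorm(kin0.aI, dispersion),
                    Gb=kin0.Gb,
                )
                subj_factor = {
                    k: math.exp(rng.normal(0.0, dispersion)) if dispersion > 0 else 1.0
                    for k in ("ka1", "ka2", "kd")
                }
                absorption = []
                for p in median_absorption:
                    fields = {}
                    for k in ("ka1", "ka2", "kd"):
                        v = getattr(p, k)
                        if v is None:
                            continue
                        f = subj_factor[k]
                        if meal_variability > 0:
                            f *= math.exp(rng.normal(0.0, meal_variability))
                        fields[k] = v * f
                    if "kd" in fields and "ka2" in fields and fields["kd"] < fields["ka2"]:
                        fields["kd"] = fields["ka2"]
                    ap = AbsorptionParams(**fields)
                    ap.validate(spec.absorption)
                    absorption.append(ap)
                subjects.append(
                    VirtualSubject(
                        kinetics=kin,
                        absorption=tuple(absorption),
                        basal_rate=basal_rate,
                        body_mass=body_mass,
                    )
                )
                break
            except DegenerateParametersError:
                if attempt == max_retries - 1:
                    raise
    return subjects
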