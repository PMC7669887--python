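"""Synthetic raw data for every stage of the multistressor pipeline.

Everything the study records can be generated here with known ground
truth: the 2x2 temperature x pCO2 factorial design with replicate holding
groups, per-shark trait values from a linear mixed generative model,
intermittent-flow respirometry O2 traces, 25-Hz tri-axial acceleration
traces, T-maze turn sequences, blood panels, and seawater acid-titration
curves.  Downstream modules are then testable by parameter recovery
against the stored truth.

Seeding: one global seed fans out through ``numpy.random.SeedSequence``
keyed on structural indices (cell, group, shark), so enlarging the design
never perturbs data already generated for existing sharks.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import carbonate
from .behaviour import AccelTrace, HypoxiaTrial, TurnRecord
from .respirometry import MASS_SCALING_EXPONENT, O2Trace

__all__ = [
    "StudyDesign",
    "Shark",
    "TraitGroundTruth",
    "RespirometerConfig",
    "MO2Truth",
    "ActivityTruth",
    "BloodTruth",
    "TitrationConfig",
    "generate_design",
    "generate_trait",
    "generate_trait_table_arrays",
    "generate_o2_trace",
    "generate_accel_trace",
    "generate_turns",
    "generate_hypoxia_trial",
    "generate_blood_panel",
    "generate_titration",
]


# --------------------------------------------------------------------------
# design and roster


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed temperature x pCO2 design with replicate holding groups."""

    temperature_levels: tuple[float, ...] = (28.0, 31.0)
    pco2_levels: tuple[float, ...] = (650.0, 1050.0)
    groups_per_cell: int = 3
    sharks_per_group: tuple[int, int] = (3, 4)  # inclusive bounds
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature_levels or not self.pco2_levels:
            raise ValueError("design must have at least one level of each factor")
        if self.groups_per_cell < 1:
            raise ValueError("need at least one replicate group per cell")
        lo, hi = self.sharks_per_group
        if not 1 <= lo <= hi:
            raise ValueError("sharks_per_group bounds must satisfy 1 <= lo <= hi")

    @property
    def cells(self) -> list[tuple[float, float]]:
        return [
            (t, p) for t in self.temperature_levels for p in self.pco2_levels
        ]


@dataclass(frozen=True)
class Shark:
    id: str
    mass: float  # kg
    total_length: float  # mm
    temperature: float  # treatment level, degC
    pco2: float  # treatment level, uatm
    group_id: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")


# observed body-size distribution of the study population
MASS_MEAN, MASS_SD = 1.0, 0.2
MASS_BOUNDS = (0.7, 1.4)
LENGTH_MEAN, LENGTH_SD = 569.2, 31.9


def _stable_key(name: str) -> int:
    """Process-independent 31-bit key for a string (unlike builtin hash)."""
    digest = hashlib.blake2s(name.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-entity generator keyed on structural indices."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def generate_design(design: StudyDesign) -> list[Shark]:
    """Roster of sharks covering every cell of the crossed design.

    Group sizes are drawn uniformly within the configured bounds; masses
    come from a truncated normal matching the observed 1.0 +- 0.2 kg
    (bounded to the observed 0.7-1.4 kg range).
    """
    roster: list[Shark] = []
    for ci, (temp, pco2) in enumerate(design.cells):
        for gi in range(design.groups_per_cell):
            g_rng = _child_rng(design.seed, 0, ci, gi)
            lo, hi = design.sharks_per_group
            n = int(g_rng.integers(lo, hi + 1))
            group_id = f"T{temp:g}_C{pco2:g}_g{gi + 1}"
            for si in range(n):
                rng = _child_rng(design.seed, 1, ci, gi, si)
                a = (MASS_BOUNDS[0] - MASS_MEAN) / MASS_SD
                b = (MASS_BOUNDS[1] - MASS_MEAN) / MASS_SD
                mass = float(
                    truncnorm.rvs(a, b, loc=MASS_MEAN, scale=MASS_SD, random_state=rng)
                )
                length = float(rng.normal(LENGTH_MEAN, LENGTH_SD))
                roster.append(
                    Shark(
                        id=f"{group_id}_s{si + 1}",
                        mass=mass,
                        total_length=length,
                        temperature=temp,
                        pco2=pco2,
                        group_id=group_id,
                    )
                )
    return roster


# --------------------------------------------------------------------------
# trait values from the linear mixed generative model


@dataclass(frozen=True)
class TraitGroundTruth:
    """Generative parameters for one trait.

    Treatment effects are specified as treatment/control *ratios*; a ratio
    r enters the (additive) linear model as a shift of (r - 1) x intercept
    applied when the corresponding factor combination is at its high
    level.  ``group_sd`` is the replicate-group random-intercept standard
    deviation and ``residual_sd`` the within-group noise.
    """

    name: str
    intercept: float
    temperature_ratio: float = 1.0
    pco2_ratio: float = 1.0
    interaction_ratio: float = 1.0
    group_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.temperature_ratio, self.pco2_ratio, self.interaction_ratio):
            if r <= 0:
                raise ValueError("effect ratios must be positive")
        if self.group_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components cannot be negative")

    def expected_value(self, high_temp: bool, high_pco2: bool) -> float:
        """Cell mean implied by the ratios (no random terms)."""
        shift = 0.0
        if high_temp:
            shift += (self.temperature_ratio - 1.0) * self.intercept
        if high_pco2:
            shift += (self.pco2_ratio - 1.0) * self.intercept
        if high_temp and high_pco2:
            shift += (self.interaction_ratio - 1.0) * self.intercept
        return self.intercept + shift


def generate_trait(
    shark: Shark,
    truth: TraitGroundTruth,
    design: StudyDesign,
    seed: int,
    group_effect: float | None = None,
) -> float:
    """One trait draw: cell mean + group intercept + residual.

    ``group_effect`` allows the caller to share a drawn group intercept
    across the sharks of a holding group; when omitted it is drawn
    deterministically from (seed, trait, group), which preserves sharing
    because the key does not involve the shark.
    """
    high_t = shark.temperature == max(design.temperature_levels) and (
        len(design.temperature_levels) > 1
    )
    high_c = shark.pco2 == max(design.pco2_levels) and len(design.pco2_levels) > 1
    mean = truth.expected_value(high_t, high_c)
    tkey = _stable_key(truth.name)
    if group_effect is None:
        g_rng = _child_rng(seed, 2, tkey, _stable_key(shark.group_id))
        group_effect = float(g_rng.normal(0.0, truth.group_sd))
    e_rng = _child_rng(seed, 3, tkey, _stable_key(shark.id))
    residual = float(e_rng.normal(0.0, truth.residual_sd))
    return mean + group_effect + residual


def generate_trait_table_arrays(
    roster: list[Shark],
    truths: list[TraitGroundTruth],
    design: StudyDesign,
    seed: int,
) -> dict[str, np.ndarray]:
    """Column arrays (one per trait) for the whole roster, sharing group draws."""
    cols: dict[str, np.ndarray] = {}
    for truth in truths:
        cols[truth.name] = np.array(
            [generate_trait(s, truth, design, seed) for s in roster]
        )
    return cols


# --------------------------------------------------------------------------
# respirometry O2 traces


@dataclass(frozen=True)
class RespirometerConfig:
    """Intermittent-flow schedule and chamber/sensor characteristics.

    The trial runs ``n_cycles`` measure/flush cycles; the default 10-min
    measure / 5-min flush cadence places 96 determinations in 24 h.
    Background (empty-chamber) phases bracket the trial.
    """

    volume: float = 25.0  # L
    o2_saturation: float = 6.8  # mg L-1, air-saturated at ~28 degC
    measure_duration: float = 600.0  # s
    flush_duration: float = 300.0  # s
    n_cycles: int = 96
    background_duration: float = 600.0  # s
    sample_interval: float = 2.0  # s
    noise_sd: float = 0.0  # mg L-1 sensor noise
    background_rate_start: float = 0.0  # mg O2 L-1 s-1 at trial start
    background_rate_end: float = 0.0  # mg O2 L-1 s-1 at trial end


@dataclass(frozen=True)
class MO2Truth:
    """True uptake kinetics behind a generated trace.

    Instantaneous mass-corrected uptake decays exponentially from
    ``mo2_max`` (post-chase) toward ``mo2_min`` (resting) with rate
    constant ``recovery_k`` (h^-1):

        mo2(t) = mo2_min + (mo2_max - mo2_min) * exp(-recovery_k * t).

    ``epoc``/``recovery_time`` give the ground truth under the same
    decay-curve convention the estimator applies (the metric is defined
    *by* that convention): because the true asymptote equals mo2_min the
    strict intersection rule never fires, and recovery is the time the
    excess falls within ``threshold_frac`` of mo2_min.
    """

    mo2_min: float = 133.69  # mg O2 kg^-b h^-1
    mo2_max: float = 360.15
    recovery_k: float = 0.5  # h^-1
    threshold_frac: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.mo2_min <= self.mo2_max:
            raise ValueError("need 0 < mo2_min <= mo2_max")
        if self.recovery_k <= 0:
            raise ValueError("recovery_k must be positive")

    @property
    def aas(self) -> float:
        return self.mo2_max - self.mo2_min

    @property
    def fas(self) -> float:
        return self.mo2_max / self.mo2_min

    @property
    def recovery_time(self) -> float:
        a = self.mo2_max - self.mo2_min
        floor = self.threshold_frac * self.mo2_min
        if a <= floor:
            return 0.0
        return math.log(a / floor) / self.recovery_k

    @property
    def epoc(self) -> float:
        a = self.mo2_max - self.mo2_min
        k = self.recovery_k
        return a / k * (1.0 - math.exp(-k * self.recovery_time))

    def mo2_at(self, t_s: float) -> float:
        return self.mo2_min + (self.mo2_max - self.mo2_min) * math.exp(
            -self.recovery_k * t_s / 3600.0
        )


def _excess_integral(a: float, k_per_s: float, t0: float, t1: float) -> float:
    """Integral of a * exp(-k t) over [t0, t1] (t in seconds)."""
    return a / k_per_s * (math.exp(-k_per_s * t0) - math.exp(-k_per_s * t1))


def generate_o2_trace(
    shark: Shark,
    truth: MO2Truth,
    config: RespirometerConfig = RespirometerConfig(),
    seed: int = 0,
) -> O2Trace:
    """Synthesise a full 24-h intermittent-flow O2 trace.

    Within each measure phase the O2 concentration falls by the exact
    integral of the instantaneous uptake (exponential recovery decay)
    plus the linearly drifting background rate; flush phases relax the
    chamber back to saturation.  Empty-chamber background phases precede
    (negative times) and follow the trial.  Gaussian sensor noise is added
    to every sample when ``noise_sd`` > 0.
    """
    if config.volume <= shark.mass / 1.0:
        raise ValueError("respirometer volume must exceed animal volume")
    rng = _child_rng(seed, 4, _stable_key(shark.id))
    dt = config.sample_interval
    veff = config.volume - shark.mass / 1.0
    k_per_s = truth.recovery_k / 3600.0
    a_conc = (
        truth.aas * shark.mass**MASS_SCALING_EXPONENT / 3600.0 / veff
    )  # mg L-1 s-1 amplitude of the decaying excess
    c_conc = truth.mo2_min * shark.mass**MASS_SCALING_EXPONENT / 3600.0 / veff
    trial_end = config.n_cycles * (config.measure_duration + config.flush_duration)

    def bg_rate(t: float) -> float:
        frac = (t + config.background_duration) / (
            trial_end + 2 * config.background_duration
        )
        return config.background_rate_start + frac * (
            config.background_rate_end - config.background_rate_start
        )

    times: list[np.ndarray] = []
    o2: list[np.ndarray] = []
    phases: list[np.ndarray] = []

    def emit(t: np.ndarray, y: np.ndarray, label: str) -> None:
        times.append(t)
        o2.append(y)
        phases.append(np.full(t.shape, label))

    # pre-trial empty chamber
    t_pre = np.arange(-config.background_duration, 0.0, dt)
    # linear-in-slope background integrates to a quadratic; do it exactly
    y_pre = config.o2_saturation - _cumulative_bg(t_pre, t_pre[0], bg_rate)
    emit(t_pre, y_pre, "background_pre")

    t = 0.0
    for _ in range(config.n_cycles):
        ts = np.arange(t, t + config.measure_duration, dt)
        drop = np.array(
            [
                _excess_integral(a_conc, k_per_s, t, tt)
                + c_conc * (tt - t)
                for tt in ts
            ]
        )
        drop += _cumulative_bg(ts, t, bg_rate)
        emit(ts, config.o2_saturation - drop, "measure")
        end_o2 = config.o2_saturation - (
            _excess_integral(a_conc, k_per_s, t, t + config.measure_duration)
            + c_conc * config.measure_duration
            + _cumulative_bg(
                np.array([t + config.measure_duration]), t, bg_rate
            )[0]
        )
        t += config.measure_duration
        tf = np.arange(t, t + config.flush_duration, dt)
        frac = (tf - t) / config.flush_duration
        emit(tf, end_o2 + (config.o2_saturation - end_o2) * frac, "flush")
        t += config.flush_duration

    t_post = np.arange(t, t + config.background_duration, dt)
    y_post = config.o2_saturation - _cumulative_bg(t_post, t_post[0], bg_rate)
    emit(t_post, y_post, "background_post")

    time = np.concatenate(times)
    conc = np.concatenate(o2)
    if config.noise_sd > 0:
        conc = conc + rng.normal(0.0, config.noise_sd, conc.shape)
    return O2Trace(
        time=time,
        o2=conc,
        phase=np.concatenate(phases),
        volume=config.volume,
        mass=shark.mass,
    )


def _cumulative_bg(ts: np.ndarray, t0: float, bg_rate) -> np.ndarray:
    """Exact integral of the linear background rate from t0 to each sample."""
    r0 = bg_rate(t0)
    # bg_rate is affine in t; recover its slope from two evaluations
    r1 = bg_rate(t0 + 1.0)
    slope = r1 - r0
    dt = ts - t0
    return r0 * dt + 0.5 * slope * dt**2


# --------------------------------------------------------------------------
# accelerometry


@dataclass(frozen=True)
class ActivityTruth:
    """Tail-beat kinematics behind an acceleration trace.

    Sustained swimming appears as a sinusoid of ``tailbeat_hz`` on each
    axis with per-axis amplitudes (g); gravity contributes a slowly
    rotating quasi-static vector.  For a pure sinusoid of amplitude A the
    rectified dynamic component averages 2A/pi, so true mean ODBA is
    sum_axes 2 A_i / pi.  That closed form assumes the running-mean static
    estimate passes none of the tail beat, which holds exactly when the
    smoothing window spans an integer number of beat cycles — the default
    1.5 Hz puts 3 cycles in a 2-s window at 25 Hz (otherwise the mean
    leaks a sinc(f T) fraction of the sinusoid and ODBA is attenuated by
    1 - sinc(f T)).
    """

    amplitudes: tuple[float, float, float] = (0.12, 0.05, 0.03)
    tailbeat_hz: float = 1.5
    gravity: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gravity_wobble: float = 0.0  # g, slow postural variation
    gravity_wobble_period: float = 120.0  # s
    noise_sd: float = 0.0

    @property
    def true_odba(self) -> float:
        return sum(2.0 * a / math.pi for a in self.amplitudes)


def generate_accel_trace(
    shark: Shark,
    truth: ActivityTruth,
    duration_s: float = 600.0,
    sampling_rate: float = 25.0,
    clock_start: float = 11 * 3600.0,
    seed: int = 0,
) -> AccelTrace:
    """Tri-axial 25-Hz acceleration trace with known mean ODBA."""
    if sampling_rate < 2.0 * truth.tailbeat_hz:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz under-samples the "
            f"{truth.tailbeat_hz} Hz tail beat"
        )
    rng = _child_rng(seed, 5, _stable_key(shark.id))
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    axes = []
    for i in range(3):
        static = truth.gravity[i] + truth.gravity_wobble * np.sin(
            2 * np.pi * t / truth.gravity_wobble_period + phases[i]
        )
        dynamic = truth.amplitudes[i] * np.sin(
            2 * np.pi * truth.tailbeat_hz * t + phases[i]
        )
        noise = rng.normal(0.0, truth.noise_sd, t.shape) if truth.noise_sd else 0.0
        axes.append(static + dynamic + noise)
    return AccelTrace(
        time=t,
        x=axes[0],
        y=axes[1],
        z=axes[2],
        sampling_rate=sampling_rate,
        clock_start=clock_start,
    )


# --------------------------------------------------------------------------
# T-maze turns and hypoxia trials


def generate_turns(
    shark: Shark,
    right_bias_p: float = 0.5,
    n_turns: int = 20,
    seed: int = 0,
) -> TurnRecord:
    """Bernoulli(right_bias_p) turn sequence, half initiated from each maze side."""
    if not 0.0 <= right_bias_p <= 1.0:
        raise ValueError("right_bias_p must be a probability")
    if n_turns % 2:
        raise ValueError("n_turns must be even (half per maze side)")
    rng = _child_rng(seed, 6, _stable_key(shark.id))
    turns = ["R" if u < right_bias_p else "L" for u in rng.uniform(size=n_turns)]
    sides = ["L", "R"] * (n_turns // 2)
    return TurnRecord(shark_id=shark.id, turns=turns, maze_sides=sides)


def generate_hypoxia_trial(
    shark: Shark,
    os_saturation: float = 24.5,
    drawdown_rate: float = 8.9,  # % air saturation per minute
    start_saturation: float = 100.0,
    sample_interval: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> HypoxiaTrial:
    """Linear O2 drawdown with the spasm-onset event at a known saturation."""
    if not 0 < os_saturation < start_saturation:
        raise ValueError("OS saturation must fall inside the drawdown range")
    rng = _child_rng(seed, 7, _stable_key(shark.id))
    total_s = (start_saturation - 0.0) / drawdown_rate * 60.0
    t = np.arange(0.0, total_s, sample_interval)
    sat = start_saturation - drawdown_rate * t / 60.0
    if noise_sd:
        sat = sat + rng.normal(0, noise_sd, sat.shape)
    os_time = (start_saturation - os_saturation) / drawdown_rate * 60.0
    return HypoxiaTrial(time=t, saturation=sat, os_time=os_time)


# --------------------------------------------------------------------------
# blood panels


@dataclass(frozen=True)
class BloodTruth:
    """True panel values; absorbances are back-computed through Beer-Lambert."""

    ph: float = 7.2
    lactate: float = 3.58  # mmol L-1
    hct: float = 0.21
    hb: float = 0.45  # mmol L-1
    hct_noise_sd: float = 0.0
    a540_noise_sd: float = 0.0

    @property
    def mchc(self) -> float:
        return self.hb / self.hct


def generate_blood_panel(shark: Shark, truth: BloodTruth, seed: int = 0):
    """Blood panel whose A540 replicates imply the true [Hb] exactly at zero noise."""
    from .haematology import (
        DEFAULT_DILUTION,
        DEFAULT_EXTINCTION,
        DEFAULT_PATH_LENGTH,
        BloodPanel,
    )

    rng = _child_rng(seed, 8, _stable_key(shark.id))
    a540_true = truth.hb * DEFAULT_EXTINCTION * DEFAULT_PATH_LENGTH / DEFAULT_DILUTION
    a540 = tuple(
        float(max(a540_true + rng.normal(0, truth.a540_noise_sd), 0.0))
        for _ in range(3)
    )
    hct = tuple(
        float(np.clip(truth.hct + rng.normal(0, truth.hct_noise_sd), 1e-3, 0.999))
        for _ in range(2)
    )
    return BloodPanel(
        shark_id=shark.id,
        ph_measured=truth.ph,
        lactate=truth.lactate,
        hct_replicates=hct,
        a540_replicates=a540,
    )


# --------------------------------------------------------------------------
# titration curves


@dataclass(frozen=True)
class TitrationConfig:
    sample_volume: float = 50.0  # mL
    acid_concentration: float = 0.1  # mol L-1
    increment: float = 0.1  # mL per dose
    temperature: float = 25.0
    salinity: float = 35.0
    dic: float = 2100.0  # umol kg-1 of the starting sample
    acid_density: float = 1.0  # kg L-1
    ph_noise_sd: float = 0.0
    end_ph: float = 2.9  # titrate until the meter reads below this


def generate_titration(
    true_ta: float,
    config: TitrationConfig = TitrationConfig(),
    seed: int = 0,
) -> carbonate.TitrationCurve:
    """Acid titration of a seawater sample with known total alkalinity.

    Each dose updates the acid/alkalinity/DIC mass balance and the pH is
    solved from the full carbonate-system model; the recorded meter pH is
    the NBS-style activity value consistent with the solver's fH
    convention, plus optional Gaussian noise.
    """
    if true_ta <= 0:
        raise ValueError("true total alkalinity must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9)))
    k = carbonate.equilibrium_constants(config.temperature, config.salinity)
    rho = carbonate.seawater_density(config.temperature, config.salinity)
    v0_l = config.sample_volume / 1000.0
    mass_sw = v0_l * rho  # kg
    alk0 = true_ta * 1e-6 * mass_sw  # mol
    dic0 = config.dic * 1e-6 * mass_sw  # mol

    volumes: list[float] = []
    ph: list[float] = []
    v = 0.0
    for _ in range(2000):
        v += config.increment
        v_l = v / 1000.0
        mass_total = mass_sw + v_l * config.acid_density
        ta_conc = (alk0 - config.acid_concentration * v_l) / mass_total
        dic_conc = dic0 / mass_total

        def residual(h: float) -> float:
            return carbonate.total_alkalinity_from_h(h, dic_conc, k) - ta_conc

        h = brentq(residual, 1e-12, 1.0, xtol=1e-18, rtol=1e-14)
        meter_ph = -math.log10(h * k.fH)
        if config.ph_noise_sd:
            meter_ph += float(rng.normal(0, config.ph_noise_sd))
        volumes.append(v)
        ph.append(meter_ph)
        if meter_ph < config.end_ph:
            break
    else:  # pragma: no cover - guarded by end_ph default
        warnings.warn("titration did not reach end pH; curve truncated")
    return carbonate.TitrationCurve(
        acid_volumes=np.array(volumes),
        ph=np.array(ph),
        sample_volume=config.sample_volume,
        acid_concentration=config.acid_concentration,
        temperature=config.temperature,
        salinity=config.salinity,
    )
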