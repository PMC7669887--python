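"""Intermittent-flow respirometry: from an O2 trace to six uptake metrics.

A 24-h trial alternates sealed *measure* phases, during which dissolved O2
declines at the animal's uptake rate, with *flush* phases that restore
aerated water.  Empty-chamber *background* phases immediately before and
after the trial measure microbial respiration.  The pipeline is:

1. one least-squares slope per measure phase -> per-interval uptake rates
   (determinations), filtered on goodness of fit (R^2 > 0.95);
2. background correction by linear interpolation between the pre and post
   background rates;
3. minimum uptake (SMR proxy) by the mean-of-the-lowest-normal-distribution
   (MLND) method: a BIC-selected Gaussian mixture over determinations,
   taking the mean of the lowest-mean component;
4. maximum uptake from the steepest 30-s regression window in the first
   hour (the post-chase recovery peak);
5. aerobic scopes AAS = max - min and FAS = max / min;
6. excess post-exercise oxygen consumption (EPOC) as the area between an
   exponential recovery curve fitted to the determinations and the minimum
   uptake rate, up to their intersection (the recovery time).

Uptake rates are reported allometrically mass-corrected to a 1-kg animal,
mg O2 kg^-b h^-1 with intraspecific scaling exponent b = 0.89.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "O2Trace",
    "MO2Determination",
    "RespirometryMetrics",
    "BackgroundRate",
    "MASS_SCALING_EXPONENT",
    "extract_determinations",
    "background_rates",
    "background_correct",
    "mo2_min_mlnd",
    "mo2_max",
    "epoc_and_recovery",
    "analyse_trace",
]

MASS_SCALING_EXPONENT = 0.89
R2_THRESHOLD = 0.95
MIN_DETERMINATIONS_MLND = 20


@dataclass
class O2Trace:
    """Dissolved-O2 time series with phase labels and chamber geometry.

    ``phase`` holds per-sample labels: ``measure``, ``flush``,
    ``background_pre`` or ``background_post``.  Animal volume defaults to
    mass at a displacement of 1.0 kg L^-1 and must leave positive
    effective (water) volume.
    """

    time: np.ndarray  # s
    o2: np.ndarray  # mg O2 L-1
    phase: np.ndarray  # str labels
    volume: float  # respirometer volume, L
    mass: float  # animal mass, kg
    animal_volume: float | None = None  # L
    temperature: float = 28.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (self.time.shape == self.o2.shape == self.phase.shape):
            raise ValueError("time, o2 and phase must align")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.volume <= 0 or self.mass <= 0:
            raise ValueError("volumes and mass must be positive")
        if self.animal_volume is None:
            self.animal_volume = self.mass / 1.0  # ~neutral density
        if self.animal_volume >= self.volume:
            raise ValueError(
                f"animal volume {self.animal_volume} L must be below the "
                f"respirometer volume {self.volume} L"
            )

    @property
    def effective_volume(self) -> float:
        """Water volume actually exchanging O2 with the animal, L."""
        return self.volume - self.animal_volume

    def segments(self, label: str):
        """Yield (start_idx, stop_idx) of contiguous runs with this phase label."""
        is_lab = self.phase == label
        if not is_lab.any():
            return
        edges = np.flatnonzero(np.diff(is_lab.astype(int)))
        starts = [0] if is_lab[0] else []
        starts += [int(e) + 1 for e in edges if is_lab[e + 1]]
        stops = [int(e) + 1 for e in edges if is_lab[e]]
        if is_lab[-1]:
            stops.append(len(is_lab))
        yield from zip(starts, stops)


@dataclass
class MO2Determination:
    """One measure-phase uptake estimate."""

    start: float  # s
    end: float  # s
    slope: float  # mg O2 L-1 s-1, signed (negative = decline)
    r_squared: float
    mo2: float  # mg O2 kg^-b h^-1
    background_corrected: bool = False
    excluded: bool = False  # negative after correction, or poor fit

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class BackgroundRate:
    """Empty-chamber O2 decline rate at a known time."""

    time: float  # s, midpoint of the background phase
    slope: float  # mg O2 L-1 s-1, signed


@dataclass
class RespirometryMetrics:
    """The six trial-level uptake metrics (mass-corrected units)."""

    mo2_min: float
    mo2_max: float
    epoc: float  # mg O2 kg^-b
    recovery_time: float  # h
    epoc_approximate: bool = False  # fallback threshold rule used
    mo2_max_inconsistent: bool = False  # mo2_max < mo2_min
    scaling_exponent: float = MASS_SCALING_EXPONENT

    @property
    def aas(self) -> float:
        return self.mo2_max - self.mo2_min

    @property
    def fas(self) -> float:
        return self.mo2_max / self.mo2_min


def _slope_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2, defining R^2 = 1 for an exact (possibly flat) fit."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    exact = 1e-20 * max(1.0, float(y @ y))  # float dust on an exact fit
    if ss_tot <= exact:
        r2 = 1.0 if ss_res <= exact else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), max(0.0, min(1.0, r2))


def _rate_to_mo2(rate: float, trace: O2Trace) -> float:
    """mg O2 L-1 s-1 consumption -> mg O2 kg^-b h-1."""
    return rate * trace.effective_volume * 3600.0 / trace.mass**MASS_SCALING_EXPONENT


def extract_determinations(
    trace: O2Trace,
    *,
    r2_threshold: float = R2_THRESHOLD,
    min_samples: int = 5,
) -> list[MO2Determination]:
    """One uptake determination per measure phase.

    Phases whose linear fit has R^2 <= ``r2_threshold`` are kept in the
    list but flagged ``excluded``; phases with fewer than ``min_samples``
    samples are skipped with a warning.
    """
    out: list[MO2Determination] = []
    for start, stop in trace.segments("measure"):
        t = trace.time[start:stop]
        y = trace.o2[start:stop]
        if t.size < min_samples:
            warnings.warn(
                f"measure phase at t={t[0] if t.size else '?'}s has "
                f"{t.size} samples (< {min_samples}); skipped",
                stacklevel=2,
            )
            continue
        slope, r2 = _slope_r2(t, y)
        out.append(
            MO2Determination(
                start=float(t[0]),
                end=float(t[-1]),
                slope=slope,
                r_squared=r2,
                mo2=_rate_to_mo2(abs(slope), trace),
                excluded=r2 <= r2_threshold,
            )
        )
    if not out:
        raise ValueError("trace contains no usable measure phases")
    return out


def background_rates(trace: O2Trace) -> tuple[BackgroundRate | None, BackgroundRate | None]:
    """Empty-chamber O2 decline slopes from the pre and post background phases."""
    rates: dict[str, BackgroundRate | None] = {}
    for label in ("background_pre", "background_post"):
        segs = list(trace.segments(label))
        if not segs:
            rates[label] = None
            continue
        start, stop = segs[0]
        t = trace.time[start:stop]
        y = trace.o2[start:stop]
        slope, _ = _slope_r2(t, y)
        rates[label] = BackgroundRate(time=float(t.mean()), slope=slope)
    return rates["background_pre"], rates["background_post"]


def background_correct(
    determinations: list[MO2Determination],
    pre: BackgroundRate | None,
    post: BackgroundRate | None,
    trace: O2Trace,
) -> list[MO2Determination]:
    """Subtract the time-interpolated background rate from each determination.

    A line is fit through the two empty-chamber rates and evaluated at each
    determination's midpoint; correction happens on the per-litre rate
    scale before conversion to mass-corrected units.  With only one
    background measurement a constant correction is applied (warning);
    with none, determinations are returned unchanged (warning).
    """
    if pre is None and post is None:
        warnings.warn("no background phases; determinations left uncorrected", stacklevel=2)
        return determinations
    if pre is None or post is None:
        only = pre or post
        warnings.warn(
            "single background measurement; applying constant correction",
            stacklevel=2,
        )

        def bg_rate(t: float) -> float:
            return -only.slope

    else:
        t0, t1 = pre.time, post.time
        r0, r1 = -pre.slope, -post.slope  # consumption rates, positive

        def bg_rate(t: float) -> float:
            return r0 + (r1 - r0) * (t - t0) / (t1 - t0)

    corrected = []
    for d in determinations:
        rate = abs(d.slope) - bg_rate(d.midpoint)
        mo2 = _rate_to_mo2(rate, trace)
        corrected.append(
            MO2Determination(
                start=d.start,
                end=d.end,
                slope=d.slope,
                r_squared=d.r_squared,
                mo2=max(mo2, 0.0) if not d.excluded else mo2,
                background_corrected=True,
                # negative corrected uptake indicates drift; exclude, don't clip
                excluded=d.excluded or mo2 < 0,
            )
        )
    return corrected


def _retained(determinations: list[MO2Determination]) -> np.ndarray:
    vals = np.array([d.mo2 for d in determinations if not d.excluded])
    return vals


def mo2_min_mlnd(
    determinations: list[MO2Determination] | np.ndarray,
    *,
    max_components: int = 4,
    random_state: int = 0,
) -> float:
    """Minimum uptake rate by the Mean of the Lowest Normal Distribution.

    Fits Gaussian mixtures with 1..``max_components`` components to the
    retained determination values, selects by BIC, and returns the mean of
    the lowest-mean component.  Rationale: resting uptake forms the lowest
    mode of the determination distribution, with spontaneous activity
    contributing higher modes.
    """
    if isinstance(determinations, np.ndarray) or isinstance(determinations, list) and determinations and isinstance(determinations[0], (int, float, np.floating)):
        values = np.asarray(determinations, dtype=float)
    else:
        values = _retained(determinations)
    if values.size < MIN_DETERMINATIONS_MLND:
        raise ValueError(
            f"only {values.size} retained determinations; MLND needs >= "
            f"{MIN_DETERMINATIONS_MLND} (consider a low-quantile fallback)"
        )
    if np.ptp(values) < 1e-12:
        return float(values[0])
    x = values.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, random_state=random_state, n_init=3, reg_covar=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_bic, best = bic, gm
    return float(best.means_.min())


def mo2_max(
    trace: O2Trace,
    *,
    window_s: float = 30.0,
    first_hour_s: float = 3600.0,
    pre: BackgroundRate | None = None,
    post: BackgroundRate | None = None,
) -> float:
    """Maximum uptake from the steepest 30-s window in the first hour.

    Windows advance sample-by-sample but never span a flush; the winning
    window's |slope| is background-corrected (when rates are supplied) and
    converted like any determination.  Ties go to the earliest window.
    """
    best_rate = None
    best_t = None
    for start, stop in trace.segments("measure"):
        t = trace.time[start:stop]
        if t[0] >= first_hour_s:
            continue
        y = trace.o2[start:stop]
        dt = np.median(np.diff(t))
        w = int(round(window_s / dt)) + 1
        if t.size < w:
            continue
        tw = sliding_window_view(t, w)
        yw = sliding_window_view(y, w)
        # keep windows fully inside the first hour
        ok = tw[:, -1] <= first_hour_s
        if not ok.any():
            continue
        tw, yw = tw[ok], yw[ok]
        tc = tw - tw.mean(axis=1, keepdims=True)
        yc = yw - yw.mean(axis=1, keepdims=True)
        slopes = (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)
        i = int(np.argmax(np.abs(slopes)))  # argmax returns first maximum
        if best_rate is None or abs(slopes[i]) > best_rate:
            best_rate = abs(slopes[i])
            best_t = float(tw[i].mean())
    if best_rate is None:
        raise ValueError("no complete 30-s window inside the first hour")
    if pre is not None and post is not None:
        bg = -pre.slope + (-post.slope + pre.slope) * (best_t - pre.time) / (
            post.time - pre.time
        )
        best_rate -= bg
    elif pre is not None or post is not None:
        best_rate -= -(pre or post).slope
    return _rate_to_mo2(best_rate, trace)


def epoc_and_recovery(
    determinations: list[MO2Determination],
    mo2_min: float,
    *,
    threshold_frac: float = 0.10,
    asymptote_tol: float = 0.01,
) -> tuple[float, float, bool]:
    """EPOC (mg O2 kg^-b) and recovery time (h) from the post-exercise decay.

    Fits y(t) = a exp(-k t) + c to the retained determinations (t in hours
    from the start of the trial, i.e. the first determination's start).
    Recovery is the earliest t with y(t) <= mo2_min (closed form when the
    asymptote c lies below mo2_min); EPOC is the analytic integral of
    y(t) - mo2_min over [0, recovery].  When the fitted asymptote does not
    undercut mo2_min by at least ``asymptote_tol`` (relative) the strict
    intersection is either absent or pushed to an arbitrarily late,
    noise-dominated crossing; recovery then falls back to the time the
    fitted excess a exp(-k t) drops within ``threshold_frac`` of mo2_min,
    and the result is flagged approximate.

    Returns (epoc, recovery_time, approximate_flag).
    """
    kept = [d for d in determinations if not d.excluded]
    if len(kept) < 4:
        raise ValueError("need >= 4 retained determinations to fit the recovery curve")
    t0 = kept[0].start
    t = (np.array([d.midpoint for d in kept]) - t0) / 3600.0
    y = np.array([d.mo2 for d in kept])

    c0 = float(y.min())
    a0 = max(float(y.max() - y.min()), 1e-6)
    k0 = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            lambda tt, a, k, c: a * np.exp(-k * tt) + c,
            t,
            y,
            p0=(a0, k0, c0),
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    a, k, c = map(float, popt)

    if a + c <= mo2_min:  # already at/below minimum at t = 0
        return 0.0, 0.0, False

    if c < mo2_min * (1.0 - asymptote_tol):
        t_star = np.log(a / (mo2_min - c)) / k
        approximate = False
    else:
        # no intersection: time for the fitted excess to fall within
        # threshold_frac of mo2_min
        floor = threshold_frac * mo2_min
        t_star = np.log(a / floor) / k if a > floor else 0.0
        approximate = True
    t_star = max(t_star, 0.0)
    epoc = a / k * (1.0 - np.exp(-k * t_star)) + (c - mo2_min) * t_star
    return float(max(epoc, 0.0)), float(t_star), approximate


def analyse_trace(trace: O2Trace) -> tuple[RespirometryMetrics, list[MO2Determination]]:
    """Full pipeline: determinations -> background correction -> six metrics."""
    dets = extract_determinations(trace)
    pre, post = background_rates(trace)
    if pre is not None or post is not None:
        dets = background_correct(dets, pre, post, trace)
    m_min = mo2_min_mlnd(dets)
    m_max = mo2_max(trace, pre=pre, post=post)
    epoc, recovery, approx = epoc_and_recovery(dets, m_min)
    metrics = RespirometryMetrics(
        mo2_min=m_min,
        mo2_max=m_max,
        epoc=epoc,
        recovery_time=recovery,
        epoc_approximate=approx,
        mo2_max_inconsistent=m_max < m_min,
    )
    return metrics, dets
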