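"""Seawater CO2-system solver and Gran-titration total alkalinity.

The carbonate system of a seawater sample is fully determined by two
measured parameters plus temperature and salinity.  Here the measured pair
is (pH on the NBS scale, total alkalinity A_T), the pair used to monitor
aquarium treatment water, and the derived quantity of interest is pCO2.

Conventions
-----------
* Carbonic-acid constants K1/K2: Mehrbach et al. (1973) as refit by
  Dickson & Millero (1987), seawater pH scale.
* Bisulfate KS: Dickson (1990a), free scale; borate KB: Dickson (1990b);
  water KW: Millero (1995); CO2 solubility K0: Weiss (1974); total boron
  proportional to salinity (Uppstrom 1974).
* pH_NBS is converted to a hydrogen-ion concentration on the seawater
  scale by dividing the activity 10**(-pH_NBS) by the Culberson/Takahashi
  activity factor fH.
* Hydrogen fluoride is excluded from the alkalinity balance by default
  (``include_fluoride`` enables it); on that convention the total and
  seawater scales coincide, so no further scale conversion is applied.

All concentrations are mol per kg of seawater unless stated otherwise;
A_T is accepted and reported in umol kg-SW^-1, pCO2 in uatm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConstantSet",
    "SeawaterSample",
    "TitrationCurve",
    "equilibrium_constants",
    "solve_pco2",
    "solve_ph",
    "gran_alkalinity",
    "seawater_density",
]

# fit ranges of the Mehrbach refit; outside them results are extrapolation
_T_RANGE = (0.0, 45.0)
_S_RANGE = (19.0, 43.0)


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants and totals at a given temperature/salinity.

    K1 > K2 always holds for carbonic acid; ``fH`` is the activity
    coefficient used to map pH_NBS onto a concentration scale.
    """

    temperature: float  # degC
    salinity: float  # practical salinity
    K0: float  # mol kg-1 atm-1
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float  # free scale
    KF: float
    BT: float  # total boron, mol kg-1
    ST: float  # total sulfate, mol kg-1
    FT: float  # total fluoride, mol kg-1
    fH: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not (self.K1 > self.K2 > 0):
            raise ValueError("carbonic-acid constants must satisfy K1 > K2 > 0")


@dataclass
class SeawaterSample:
    """One water sample: measured state plus solved CO2-system outputs."""

    temperature: float  # degC
    salinity: float
    ph_nbs: float
    alkalinity: float  # umol kg-SW^-1
    pco2: float | None = None  # uatm, filled by solve_pco2
    dic: float | None = None  # umol kg-SW^-1

    def __post_init__(self) -> None:
        if not 0 < self.salinity < 50:
            raise ValueError(f"salinity {self.salinity} outside (0, 50)")
        if self.alkalinity <= 0:
            raise ValueError("total alkalinity must be positive")


@dataclass
class TitrationCurve:
    """Open-cell acid titration record of a seawater sample.

    ``acid_volumes`` are cumulative additions (mL) of HCl at
    ``acid_concentration`` (mol L-1) into ``sample_volume`` mL of seawater.
    """

    acid_volumes: np.ndarray  # mL, strictly increasing
    ph: np.ndarray  # meter pH (NBS-like) per addition
    sample_volume: float = 50.0  # mL
    acid_concentration: float = 0.1  # mol L-1
    temperature: float = 25.0
    salinity: float = 35.0

    def __post_init__(self) -> None:
        self.acid_volumes = np.asarray(self.acid_volumes, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.acid_volumes.shape != self.ph.shape:
            raise ValueError("acid_volumes and ph must align")
        if np.any(np.diff(self.acid_volumes) <= 0):
            raise ValueError("acid volumes must be strictly increasing")
        if self.sample_volume <= 0 or self.acid_concentration <= 0:
            raise ValueError("sample volume and acid concentration must be positive")


def seawater_density(temperature: float, salinity: float) -> float:
    """Surface seawater density (kg L-1), Millero & Poisson (1981)."""
    t = temperature
    s = salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return (rho_w + a * s + b * s**1.5 + c * s**2) / 1000.0


def equilibrium_constants(temperature: float, salinity: float) -> ConstantSet:
    """Evaluate the constant set at in-situ temperature (degC) and salinity.

    Outside the Mehrbach-refit fit ranges (T 0-45 degC, S 19-43) a warning
    is issued and the returned set is flagged ``extrapolated``.
    """
    extrapolated = not (
        _T_RANGE[0] <= temperature <= _T_RANGE[1]
        and _S_RANGE[0] <= salinity <= _S_RANGE[1]
    )
    if extrapolated:
        warnings.warn(
            f"T={temperature} degC, S={salinity} outside constant fit ranges; "
            "extrapolating",
            stacklevel=2,
        )
    tk = temperature + 273.15
    s = salinity
    ln_tk = np.log(tk)

    # Weiss 1974 CO2 solubility, mol kg-1 atm-1
    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * np.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    k0 = np.exp(ln_k0)

    # Mehrbach refit by Dickson & Millero 1987, seawater scale
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * ln_tk - 0.0118 * s + 0.000116 * s**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * s + 0.000118 * s**2
    k1 = 10.0**-pk1
    k2 = 10.0**-pk2

    # Dickson 1990b borate (total scale; == seawater scale with HF excluded)
    sqs = np.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / tk
        + 148.0248
        + 137.1942 * sqs
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqs - 0.2474 * s) * ln_tk
        + 0.053105 * sqs * tk
    )
    kb = np.exp(ln_kb)

    # Millero 1995 water, seawater scale
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sqs
        - 0.01615 * s
    )
    kw = np.exp(ln_kw)

    # Dickson 1990a bisulfate, free scale, mol kg-SW^-1
    ion_s = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * ln_tk
        + (-13856.0 / tk + 324.57 - 47.986 * ln_tk) * np.sqrt(ion_s)
        + (35474.0 / tk - 771.54 + 114.723 * ln_tk) * ion_s
        - (2698.0 / tk) * ion_s**1.5
        + (1776.0 / tk) * ion_s**2
        + np.log(1.0 - 0.001005 * s)
    )
    ks = np.exp(ln_ks)

    # Dickson & Riley 1979 HF, free scale
    ln_kf = 1590.2 / tk - 12.641 + 1.525 * np.sqrt(ion_s) + np.log(1.0 - 0.001005 * s)
    kf = np.exp(ln_kf)

    bt = 0.0004157 * s / 35.0  # Uppstrom 1974
    st = 0.02824 * s / 35.0  # Morris & Riley 1966
    ft = 0.00007 * s / 35.0  # Riley 1965

    # Takahashi et al. 1982 (GEOSECS) NBS activity factor
    fh = 1.2948 - 0.002036 * tk + (0.0004607 - 0.000001475 * tk) * s**2

    return ConstantSet(
        temperature=temperature,
        salinity=salinity,
        K0=float(k0),
        K1=float(k1),
        K2=float(k2),
        KB=float(kb),
        KW=float(kw),
        KS=float(ks),
        KF=float(kf),
        BT=float(bt),
        ST=float(st),
        FT=float(ft),
        fH=float(fh),
        extrapolated=extrapolated,
    )


def _non_carbonate_alkalinity(
    h: float, k: ConstantSet, include_fluoride: bool
) -> float:
    """Borate + hydroxide - free H - bisulfate (- HF), mol kg-1.

    ``h`` is the hydrogen-ion concentration on the working (seawater)
    scale.  The free concentration is recovered through the sulfate ratio.
    """
    h_free = h / (1.0 + k.ST / k.KS)
    b_alk = k.BT * k.KB / (k.KB + h)
    oh = k.KW / h
    hso4 = k.ST * h_free / (k.KS + h_free)
    hf = k.FT * h_free / (k.KF + h_free) if include_fluoride else 0.0
    return b_alk + oh - h_free - hso4 - hf


def solve_pco2(
    sample: SeawaterSample, *, include_fluoride: bool = False
) -> SeawaterSample:
    """Solve pCO2 (uatm) and DIC from (pH_NBS, A_T, T, S); fills the sample.

    The measured pH fixes [H+]; total alkalinity then partitions into
    carbonate alkalinity after removing borate/water/sulfate contributions,
    which yields the carbonate speciation directly.
    """
    k = equilibrium_constants(sample.temperature, sample.salinity)
    h = 10.0 ** (-sample.ph_nbs) / k.fH
    ta = sample.alkalinity * 1e-6
    ca = ta - _non_carbonate_alkalinity(h, k, include_fluoride)
    if ca <= 0:
        raise ValueError(
            "non-physical carbonate alkalinity "
            f"(pH_NBS={sample.ph_nbs}, A_T={sample.alkalinity}, "
            f"T={sample.temperature}, S={sample.salinity})"
        )
    # CA = DIC (K1 h + 2 K1 K2) / (h^2 + K1 h + K1 K2)
    denom = k.K1 * h + 2.0 * k.K1 * k.K2
    dic = ca * (h**2 + k.K1 * h + k.K1 * k.K2) / denom
    co2_star = ca * h**2 / denom
    sample.pco2 = float(co2_star / k.K0 * 1e6)
    sample.dic = float(dic * 1e6)
    return sample


def total_alkalinity_from_h(
    h: float,
    dic: float,
    k: ConstantSet,
    *,
    include_fluoride: bool = False,
) -> float:
    """A_T (mol kg-1) implied by [H+] (seawater scale) and DIC (mol kg-1)."""
    denom = h**2 + k.K1 * h + k.K1 * k.K2
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    return hco3 + 2.0 * co3 + _non_carbonate_alkalinity(h, k, include_fluoride)


def solve_ph(
    alkalinity: float,
    temperature: float,
    salinity: float,
    *,
    pco2: float | None = None,
    dic: float | None = None,
    include_fluoride: bool = False,
) -> float:
    """pH_NBS from A_T (umol kg-1) plus either pCO2 (uatm) or DIC (umol kg-1).

    Inverse of :func:`solve_pco2`; used for round-trip checks and to
    synthesise titration curves.  Root-bracketed on [H+] in [1e-12, 1].
    """
    if (pco2 is None) == (dic is None):
        raise ValueError("supply exactly one of pco2 or dic")
    k = equilibrium_constants(temperature, salinity)
    ta = alkalinity * 1e-6

    if pco2 is not None:
        co2_star = k.K0 * pco2 * 1e-6

        def residual(h: float) -> float:
            hco3 = k.K1 * co2_star / h
            co3 = k.K1 * k.K2 * co2_star / h**2
            return (
                hco3 + 2.0 * co3 + _non_carbonate_alkalinity(h, k, include_fluoride)
            ) - ta

    else:
        dic_mol = dic * 1e-6

        def residual(h: float) -> float:
            return total_alkalinity_from_h(
                h, dic_mol, k, include_fluoride=include_fluoride
            ) - ta

    h = brentq(residual, 1e-12, 1.0, xtol=1e-18, rtol=1e-14)
    return float(-np.log10(h * k.fH))


def gran_alkalinity(
    curve: TitrationCurve,
    *,
    ph_window: tuple[float, float] = (3.0, 3.5),
) -> float:
    """Total alkalinity (umol kg-SW^-1) from an open-cell Gran titration.

    Within the acid region (default pH 3.0-3.5, past the second equivalence
    point where CO2 has degassed) the Gran function

        F(V) = (V0 + V) * 10**(-pH)

    is linear in added acid volume V; its x-intercept is the equivalence
    volume Ve and A_T = Ve * C_acid / (V0 * rho_sw).
    """
    if curve.ph.min() > 3.5:
        raise ValueError(
            "titration does not pass the second equivalence point (min pH "
            f"{curve.ph.min():.2f} > 3.5); add more acid"
        )
    lo, hi = ph_window
    mask = (curve.ph >= lo) & (curve.ph <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} titration points in the Gran window "
            f"pH [{lo}, {hi}]; need >= 3"
        )
    v = curve.acid_volumes[mask]
    f = (curve.sample_volume + v) * 10.0 ** (-curve.ph[mask])
    slope, intercept = np.polyfit(v, f, 1)
    ve = -intercept / slope  # mL
    if ve <= 0:
        raise ValueError("negative equivalence volume; titration data ill-posed")
    rho = seawater_density(curve.temperature, curve.salinity)
    v0_l = curve.sample_volume / 1000.0
    ve_l = ve / 1000.0
    return float(ve_l * curve.acid_concentration / (v0_l * rho) * 1e6)
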