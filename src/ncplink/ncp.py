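"""Mixed-layer O2/Ar net community production (NCP) fluxes.

Under steady state and neglecting vertical mixing, the biological oxygen
flux out of the mixed layer equals net community production:

    Delta(O2/Ar) = [(O2/Ar)_sample / (O2/Ar)_sat - 1] * 100          (percent)
    NCP_O2       = k * [O2]_sat * Delta(O2/Ar) / 100    (mmol O2 m-2 day-1)
    NCP_C        = NCP_O2 / PQ                          (mmol C m-2 day-1)

where k is the gas-transfer (piston) velocity for O2 weighted over the
recent wind history, [O2]_sat the equilibrium O2 concentration, and PQ the
photosynthetic quotient (mol O2 per mol C, default 1.4).

The argon normalization removes solubility-driven (physical) O2 anomalies,
so Delta(O2/Ar) isolates the biological supersaturation. The O2 residence
time in the mixed layer is MLD / k, and NCP normalized to the mixed-layer
POC concentration gives an export-potential index in m day-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StationRecord",
    "NcpResult",
    "MldUndefinedError",
    "delta_o2ar",
    "o2_saturation_per_mass",
    "o2_saturation_concentration",
    "schmidt_number_o2",
    "piston_velocity",
    "weighted_piston_velocity",
    "mixed_layer_depth",
    "compute_ncp",
    "residence_time",
    "normalize_ncp",
    "station_ncp",
]

#: Garcia & Gordon (1992) combined fit to the Benson & Krause O2 solubility
#: data, output in umol O2 per kg of seawater.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7

#: Schmidt number polynomial for O2 in seawater (S=35), valid 0..40 degC.
_SC_COEF = (1920.4, -135.6, 5.2122, -0.10939, 0.00093777)

#: quadratic gas-transfer coefficient, cm hr-1 per (m s-1)^2 — the widely
#: used reanalysis-wind calibration of the short-term quadratic law.
DEFAULT_GAS_TRANSFER_COEFF = 0.251
DEFAULT_PQ = 1.4
MLD_DENSITY_THRESHOLD = 0.03  # kg m-3 offset from the shallowest level

_CMHR_TO_MDAY = 24.0 / 100.0


class MldUndefinedError(ValueError):
    """The density threshold is never crossed within the profile."""


@dataclass
class StationRecord:
    """One station's environmental state used to compute its NCP."""

    station_id: str
    timestamp: str
    temperature: float          # degC
    salinity: float             # PSU
    o2ar_sample: float          # measured O2/Ar ratio
    o2ar_sat: float             # equilibrium O2/Ar ratio at T, S
    mld: float                  # m
    mixed_layer_density: float  # kg m-3
    wind_history: np.ndarray    # daily u10 (m s-1), most recent last
    poc: float                  # mmol C m-3
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        self.wind_history = np.asarray(self.wind_history, dtype=float)
        if self.temperature <= -2.0:
            raise ValueError(f"{self.station_id}: temperature below seawater range")
        if self.salinity <= 0:
            raise ValueError(f"{self.station_id}: non-positive salinity")
        if self.o2ar_sat <= 0:
            raise ValueError(f"{self.station_id}: non-positive O2/Ar saturation ratio")
        if self.mld <= 0:
            raise ValueError(f"{self.station_id}: non-positive MLD")
        if self.poc <= 0:
            raise ValueError(f"{self.station_id}: non-positive POC")
        if self.wind_history.ndim != 1 or self.wind_history.size == 0:
            raise ValueError(f"{self.station_id}: empty wind history")


@dataclass
class NcpResult:
    """Per-station fluxes and derived quantities."""

    station_id: str
    delta_o2ar: float        # percent
    o2sat_conc: float        # mmol O2 m-3
    schmidt: float           # dimensionless
    k_daily: np.ndarray      # m day-1
    k_weighted: float        # m day-1
    ncp_o2: float            # mmol O2 m-2 day-1
    ncp_c: float             # mmol C m-2 day-1
    residence_days: float    # days
    ncp_over_poc: float      # m day-1


def delta_o2ar(sample_ratio: float, sat_ratio: float) -> float:
    """Biological O2 supersaturation in percent: (sample/sat - 1) * 100."""
    if np.any(np.asarray(sat_ratio) <= 0):
        raise ValueError("saturation O2/Ar ratio must be positive")
    return (np.asarray(sample_ratio) / sat_ratio - 1.0) * 100.0


def o2_saturation_per_mass(temperature, salinity):
    """Equilibrium O2 concentration in umol per kg (Garcia-Gordon fit,
    Benson-Krause scale)."""
    T = np.asarray(temperature, dtype=float)
    S = np.asarray(salinity, dtype=float)
    if np.any(T < -2.0) or np.any(T > 40.0) or np.any(S < 0.0) or np.any(S > 42.0):
        warnings.warn("T/S outside the solubility fit's validity range",
                      stacklevel=2)
    Ts = np.log((298.15 - T) / (273.15 + T))
    lnc = sum(a * Ts ** i for i, a in enumerate(_GG_A))
    lnc = lnc + S * sum(b * Ts ** i for i, b in enumerate(_GG_B))
    lnc = lnc + _GG_C0 * S ** 2
    return np.exp(lnc)


def o2_saturation_concentration(temperature, salinity, density) -> float:
    """Volumetric equilibrium O2 concentration, mmol O2 m-3.

    The solubility fit is per unit mass; multiplying by the mixed-layer
    density (kg m-3) / 1000 converts umol kg-1 to mmol m-3. This carries the
    density factor of the flux equation, so :func:`compute_ncp` takes the
    volumetric concentration directly.
    """
    return o2_saturation_per_mass(temperature, salinity) * np.asarray(density) / 1000.0


def schmidt_number_o2(temperature) -> float:
    """Schmidt number of O2 in seawater as a polynomial in temperature."""
    T = np.asarray(temperature, dtype=float)
    return sum(c * T ** i for i, c in enumerate(_SC_COEF))


def piston_velocity(u10, temperature,
                    coeff: float = DEFAULT_GAS_TRANSFER_COEFF,
                    schmidt: Callable = schmidt_number_o2):
    """Gas-transfer velocity k in m day-1 from the quadratic wind-speed law.

    k = coeff * u10^2 * (Sc/660)^(-1/2), with coeff in cm hr-1 (m s-1)^-2.
    ``schmidt`` is injectable so alternative Schmidt formulations (or a
    fixed Sc=660 reference) can be used.
    """
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("negative wind speed")
    sc = schmidt(temperature)
    k_cmhr = coeff * u ** 2 * (sc / 660.0) ** -0.5
    return k_cmhr * _CMHR_TO_MDAY


def weighted_piston_velocity(k_daily: Sequence[float], mld: float) -> float:
    """Ventilation-weighted piston velocity over the recent wind history.

    Walking backward from the sampling day (last element), each day i
    receives weight w_i = prod_{j>i} (1 - f_j) with f_j = min(k_j dt / MLD, 1),
    dt = 1 day: the fraction of the mixed layer not yet ventilated by more
    recent days. The result is sum(w k) / sum(w).
    """
    k = np.asarray(k_daily, dtype=float)
    if k.size == 0:
        raise ValueError("empty piston-velocity series")
    if np.any(k < 0):
        raise ValueError("negative piston velocity in series")
    if mld <= 0:
        raise ValueError("MLD must be positive")
    f = np.minimum(k / mld, 1.0)
    # w_i = prod over j > i of (1 - f_j); most recent day has weight 1
    rev = np.concatenate(([1.0], np.cumprod((1.0 - f[::-1]))[:-1]))
    w = rev[::-1]
    return float(np.sum(w * k) / np.sum(w))


def mixed_layer_depth(depths: Sequence[float], sigma_theta: Sequence[float],
                      threshold: float = MLD_DENSITY_THRESHOLD) -> float:
    """MLD as the shallowest depth where sigma-theta exceeds the surface
    (shallowest-level) value by ``threshold``, linearly interpolated.

    Raises :class:`MldUndefinedError` when the threshold is never crossed.
    """
    z = np.asarray(depths, dtype=float)
    s = np.asarray(sigma_theta, dtype=float)
    if z.size != s.size or z.size < 2:
        raise ValueError("profile needs >= 2 (depth, sigma-theta) levels")
    if np.any(np.diff(z) <= 0):
        raise ValueError("profile depths must be strictly increasing")
    excess = s - s[0]
    above = np.nonzero(excess >= threshold)[0]
    if above.size == 0:
        raise MldUndefinedError(
            f"density never exceeds surface value by {threshold} kg m-3")
    i = above[0]
    if i == 0:  # cannot happen (excess[0] == 0 < threshold) unless threshold <= 0
        return float(z[0])
    frac = (threshold - excess[i - 1]) / (excess[i] - excess[i - 1])
    return float(z[i - 1] + frac * (z[i] - z[i - 1]))


def compute_ncp(k_weighted: float, o2sat_conc: float, delta_pct: float,
                pq: float = DEFAULT_PQ) -> tuple[float, float]:
    """NCP in O2 and carbon units from the weighted k, [O2]_sat and Delta(O2/Ar).

    Returns ``(ncp_o2, ncp_c)`` with ncp_o2 = k * [O2]_sat * Delta/100 and
    ncp_c = ncp_o2 / pq.
    """
    if pq <= 0:
        raise ValueError("photosynthetic quotient must be positive")
    if k_weighted < 0:
        raise ValueError("piston velocity must be nonnegative")
    if o2sat_conc <= 0:
        raise ValueError("[O2]_sat must be positive")
    ncp_o2 = k_weighted * o2sat_conc * delta_pct / 100.0
    return ncp_o2, ncp_o2 / pq


def residence_time(mld: float, k_weighted: float) -> float:
    """O2 residence time in the mixed layer: MLD / k, in days."""
    if k_weighted <= 0:
        raise ValueError("piston velocity must be positive")
    return mld / k_weighted


def normalize_ncp(ncp_c: float, poc: float) -> float:
    """NCP/POC in m day-1 — biomass-normalized export potential."""
    if poc <= 0:
        raise ValueError("POC must be positive")
    return ncp_c / poc


def station_ncp(record: StationRecord, pq: float = DEFAULT_PQ,
                gas_transfer_coeff: float = DEFAULT_GAS_TRANSFER_COEFF) -> NcpResult:
    """Full per-station chain: supersaturation -> weighted k -> fluxes."""
    delta = float(delta_o2ar(record.o2ar_sample, record.o2ar_sat))
    o2sat = float(o2_saturation_concentration(
        record.temperature, record.salinity, record.mixed_layer_density))
    sc = float(schmidt_number_o2(record.temperature))
    k_daily = piston_velocity(record.wind_history, record.temperature,
                              coeff=gas_transfer_coeff)
    k_w = weighted_piston_velocity(k_daily, record.mld)
    ncp_o2, ncp_c = compute_ncp(k_w, o2sat, delta, pq=pq)
    res = residence_time(record.mld, k_w)
    return NcpResult(
        station_id=record.station_id,
        delta_o2ar=delta,
        o2sat_conc=o2sat,
        schmidt=sc,
        k_daily=k_daily,
        k_weighted=k_w,
        ncp_o2=ncp_o2,
        ncp_c=ncp_c,
        residence_days=res,
        ncp_over_poc=normalize_ncp(ncp_c, record.poc),
    )
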