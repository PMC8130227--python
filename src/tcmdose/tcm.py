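"""Tube current modulation (TCM) schemes.

Two schemes are modeled:

* **ATCM** (attenuation-based automatic TCM, CAREDose4D-style): the
  longitudinal current at table position ``i`` follows

      A_max(i) = max(exp(mu_w * AP(i)), exp(mu_w * LAT(i)))
      mA(i)    = QRM * pitch / t * (A_max(i) / A_ref)**b

  with strength exponent ``b = 0.33`` above the reference attenuation and
  ``0.5`` below it, and an angular modulation floor

      m(i) = 1 - mu(i) * (A_max^q - A(i - hROT)^q) / (A_max^q - A_min^q)

  evaluated over the previous half rotation of table travel
  (``hROT = collimation * pitch / 2``).  The full scheme is the product of the
  longitudinal current and an angular weight that dips to ``m(i)`` at the
  AP/PA directions and reaches 1 laterally:
  ``w(i, theta) = m(i) + (1 - m(i)) * sin(theta)**2``.

* **OBTCM** (organ-based TCM, XCARE-style): the current of a base scheme is
  reduced by a factor ``r`` over a 120 degree anterior sector and, optionally,
  raised over the remaining arc so the per-rotation mean current is preserved.

Angle convention: theta = 0 is anterior (x-ray tube above a supine patient),
increasing toward patient-left; the angular grid covers [0, 2*pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Topogram",
    "ATCMParams",
    "AttenuationProfile",
    "TCMScheme",
    "longitudinal_atcm",
    "attenuation_profile",
    "angular_modulation",
    "compose_atcm",
    "apply_obtcm",
    "normalize_weights",
    "read_tcm_table",
    "write_tcm_table",
]


@dataclass(frozen=True)
class Topogram:
    """Per-table-position water-equivalent AP and LAT dimensions (cm)."""

    table_positions: np.ndarray  # cm, uniform grid
    ap: np.ndarray  # cm water-equivalent
    lat: np.ndarray  # cm water-equivalent

    def __post_init__(self):
        tp = np.asarray(self.table_positions, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        if not (tp.shape == ap.shape == lat.shape):
            raise ValueError("table_positions, ap and lat must have equal length")
        if np.any(ap < 0) or np.any(lat < 0):
            raise ValueError("water-equivalent dimensions must be non-negative")
        object.__setattr__(self, "table_positions", tp)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "lat", lat)


@dataclass(frozen=True)
class ATCMParams:
    """Protocol constants driving the ATCM prediction.

    ``a_ref`` is the scanner's hard-coded reference attenuation; the default
    anchors it to a 24-cm water-equivalent adult at mu_water = 0.2/cm.
    """

    mu_water: float = 0.2  # cm^-1 at 120 kVp
    qrm: float = 140.0  # quality reference effective mAs
    rotation_time: float = 0.5  # s
    pitch: float = 0.6
    a_ref: float = math.exp(0.2 * 24.0)
    b_over: float = 0.33
    b_under: float = 0.5
    q: float = 0.75  # angular optimization exponent, in [0.5, 1.0]
    mu_limit: float = 0.9  # modulation-depth limit mu(i) for t = 0.5 s
    collimation: float = 5.76  # cm
    ma_min: float = 20.0
    ma_max: float = 800.0

    @property
    def h_rot(self) -> float:
        """Table travel per half gantry rotation, cm."""
        return self.collimation * self.pitch / 2.0

    def __post_init__(self):
        if self.a_ref <= 0:
            raise ValueError("a_ref must be positive")
        if not 0.0 <= self.mu_limit <= 1.0:
            raise ValueError("mu_limit must lie in [0, 1]")


@dataclass(frozen=True)
class AttenuationProfile:
    """Half-rotation-window attenuation statistics per table position."""

    a_max: np.ndarray
    a_min: np.ndarray
    a_lag: np.ndarray  # A(i - hROT)


@dataclass(frozen=True)
class TCMScheme:
    """Tube current I(z, theta) on a table-position x gantry-angle grid."""

    table_positions: np.ndarray  # cm
    angle_bins: np.ndarray  # radians in [0, 2*pi), uniform
    current: np.ndarray  # mA, shape (n_positions, n_angles)
    provenance: str = "file"

    def __post_init__(self):
        cur = np.asarray(self.current, dtype=float)
        if cur.shape != (len(self.table_positions), len(self.angle_bins)):
            raise ValueError("current grid shape must be (n_positions, n_angles)")
        if np.any(cur < 0):
            raise ValueError("tube current must be non-negative")
        object.__setattr__(self, "table_positions", np.asarray(self.table_positions, float))
        object.__setattr__(self, "angle_bins", np.asarray(self.angle_bins, float))
        object.__setattr__(self, "current", cur)

    @property
    def rotation_mean(self) -> np.ndarray:
        """Per-rotation (angle-averaged) current at each table position."""
        return self.current.mean(axis=1)


def longitudinal_atcm(topo: Topogram, params: ATCMParams, return_a_max: bool = False):
    """Per-position longitudinal tube current (mA) from the topogram."""
    a_max = np.maximum(
        np.exp(params.mu_water * topo.ap), np.exp(params.mu_water * topo.lat)
    )
    b = np.where(a_max > params.a_ref, params.b_over, params.b_under)
    ma = params.qrm * params.pitch / params.rotation_time * (a_max / params.a_ref) ** b
    ma = np.clip(ma, params.ma_min, params.ma_max)
    if return_a_max:
        return ma, a_max
    return ma


def attenuation_profile(topo: Topogram, params: ATCMParams) -> AttenuationProfile:
    """Windowed attenuation statistics over the previous half rotation.

    The per-position attenuation is A_max(i) from the topogram; the window
    covers table travel of one hROT behind the current position (clamped at
    the scan start).
    """
    _, a = longitudinal_atcm(topo, params, return_a_max=True)
    z = topo.table_positions
    n = len(z)
    a_mx = np.empty(n)
    a_mn = np.empty(n)
    a_lag = np.empty(n)
    for i in range(n):
        in_win = (z >= z[i] - params.h_rot) & (z <= z[i])
        w = a[in_win]
        a_mx[i] = w.max()
        a_mn[i] = w.min()
        a_lag[i] = np.interp(max(z[i] - params.h_rot, z[0]), z, a)
    return AttenuationProfile(a_max=a_mx, a_min=a_mn, a_lag=a_lag)


def angular_modulation(profile: AttenuationProfile, params: ATCMParams) -> np.ndarray:
    """Angular modulation floor m(i) in [1 - mu(i), 1]."""
    num = profile.a_max**params.q - profile.a_lag**params.q
    den = profile.a_max**params.q - profile.a_min**params.q
    m = np.ones_like(profile.a_max)
    ok = den > 0
    m[ok] = 1.0 - params.mu_limit * num[ok] / den[ok]
    return np.clip(m, 1.0 - params.mu_limit, 1.0)


def compose_atcm(
    topo: Topogram, params: ATCMParams, n_angle_bins: int = 36
) -> TCMScheme:
    """Full predicted ATCM scheme: longitudinal current x angular weight."""
    ma = longitudinal_atcm(topo, params)
    m = angular_modulation(attenuation_profile(topo, params), params)
    theta = np.arange(n_angle_bins) * 2.0 * np.pi / n_angle_bins
    w = m[:, None] + (1.0 - m[:, None]) * np.sin(theta)[None, :] ** 2
    return TCMScheme(
        table_positions=topo.table_positions,
        angle_bins=theta,
        current=ma[:, None] * w,
        provenance="predicted_atcm",
    )


def _anterior_fraction(angle_bins: np.ndarray, sector_deg: float) -> np.ndarray:
    """Fraction of each angular cell lying inside the anterior sector.

    Cells are the intervals of width 2*pi/n centred on the bin angles; the
    sector has hard edges at +/- sector/2 about theta = 0 (the boundary angle
    itself belongs to the anterior side, a measure-zero convention).
    """
    n = len(angle_bins)
    width = 2.0 * np.pi / n
    half = math.radians(sector_deg) / 2.0
    # distance of the cell centre from the anterior axis
    dist = np.abs((angle_bins + np.pi) % (2.0 * np.pi) - np.pi)
    lo = dist - width / 2.0
    hi = dist + width / 2.0
    overlap = np.clip(half - lo, 0.0, width)
    return np.where(hi <= half, 1.0, overlap / width)


def apply_obtcm(
    base: TCMScheme,
    reduction_r: float = 0.25,
    sector_deg: float = 120.0,
    compensate: bool = True,
    ma_max: float | None = None,
) -> TCMScheme:
    """Organ-based scheme: scale the anterior sector by ``reduction_r``.

    With ``compensate=True`` the posterior arc is raised so that each table
    position's per-rotation mean current is preserved exactly; for an
    angle-flat base this reduces to the closed-form factor
    ``c = (1 - f*r) / (1 - f)`` with ``f = sector/360``.  Whether the
    clinical implementation preserves scanner output is not publicly
    documented, hence the flag.  Pass ``ma_max`` to additionally enforce a
    tube-current clamp (which may break exact compensation at the limit).
    """
    if not 0.0 < reduction_r <= 1.0:
        raise ValueError("reduction_r must lie in (0, 1]")
    if not 0.0 < sector_deg < 360.0:
        raise ValueError("sector_deg must lie in (0, 360)")
    frac = _anterior_fraction(base.angle_bins, sector_deg)
    n = len(base.angle_bins)
    anterior_part = (base.current * frac[None, :]).sum(axis=1) / n
    posterior_part = (base.current * (1.0 - frac)[None, :]).sum(axis=1) / n
    if compensate:
        mean_i = base.current.mean(axis=1)
        c_i = np.ones_like(mean_i)
        ok = posterior_part > 0
        c_i[ok] = (mean_i[ok] - reduction_r * anterior_part[ok]) / posterior_part[ok]
    else:
        c_i = np.ones(base.current.shape[0])
    scale = frac[None, :] * reduction_r + (1.0 - frac)[None, :] * c_i[:, None]
    current = base.current * scale
    if ma_max is not None:
        current = np.minimum(current, ma_max)
    return replace(base, current=current, provenance="modeled_obtcm")


def normalize_weights(scheme: TCMScheme) -> np.ndarray:
    """Currents divided by the global maximum; MC history weights in (0, 1]."""
    peak = scheme.current.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero scheme")
    return scheme.current / peak


def write_tcm_table(scheme: TCMScheme, path) -> None:
    pos, ang = np.meshgrid(scheme.table_positions, np.degrees(scheme.angle_bins), indexing="ij")
    pd.DataFrame(
        {
            "table_position_cm": pos.ravel(),
            "angle_deg": ang.ravel(),
            "current_mA": scheme.current.ravel(),
        }
    ).to_csv(path, index=False)


def read_tcm_table(path) -> TCMScheme:
    df = pd.read_csv(path)
    required = ["table_position_cm", "angle_deg", "current_mA"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"TCM table missing column {col!r}")
    bad = np.flatnonzero(df["current_mA"].to_numpy() < 0)
    if bad.size:
        raise ValueError(f"negative tube current at row {bad[0]}")
    positions = np.unique(df["table_position_cm"].to_numpy())
    angles_deg = np.unique(df["angle_deg"].to_numpy())
    if len(df) != len(positions) * len(angles_deg):
        raise ValueError("TCM table is not a rectangular position x angle grid")
    grid = (
        df.pivot(index="table_position_cm", columns="angle_deg", values="current_mA")
        .sort_index()
        .to_numpy()
    )
    if np.any(np.isnan(grid)):
        raise ValueError("TCM table is not a rectangular position x angle grid")
    return TCMScheme(
        table_positions=positions,
        angle_bins=np.radians(angles_deg),
        current=grid,
        provenance="file",
    )
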