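"""Organ doses, CTDIvol and the normalized-dose comparison metric.

Organ dose is the mass-weighted mean dose over an organ mask.  CTDIvol for a
simulated scheme is the scanner's measured dose-index output per mAs (a
protocol constant) times the scan-averaged per-rotation mAs.  Normalized
dose nD = D / CTDIvol removes the scanner-output scale so organ doses from
different schemes and scanners can be compared; the within-patient contrast

    delta = 100 * (nD_obtcm - nD_atcm) / nD_atcm   [percent]

is negative when the organ-based scheme saves dose.  Because the MC tallies
enter both D and (through the scheme) the comparison identically, nD ratios
are independent of the absolute Monte Carlo dose calibration; organ doses
here stay in per-history units and only ratios are ever compared to
measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantoms import VoxelPhantom
from .tcm import TCMScheme
from .transport import DoseTally

__all__ = [
    "ScannerModel",
    "OrganDoseResult",
    "organ_dose",
    "ctdivol_from_scheme",
    "normalized_dose",
    "delta_percent",
    "round_half_away",
]


@dataclass(frozen=True)
class ScannerModel:
    """Scanner output constants for one protocol (per effective mAs)."""

    name: str  # "Force" or "Flash"
    kvp: float
    ctdi_per_mas: float  # mGy per effective mAs
    collimation: float  # cm
    pitch: float = 0.6
    rotation_time: float = 0.5

    def __post_init__(self):
        if self.ctdi_per_mas <= 0:
            raise ValueError("ctdi_per_mas must be positive")


@dataclass(frozen=True)
class OrganDoseResult:
    organ: str  # "breast" | "lung"
    scheme: str  # "obtcm" | "atcm"
    dose: float  # per-history energy/mass units
    ctdivol: float  # mGy
    nd: float  # dose / ctdivol
    se_rel: float  # relative MC standard error of the organ dose


def organ_dose(tally: DoseTally, phantom: VoxelPhantom, organ_mask: np.ndarray) -> float:
    """Mass-weighted mean organ dose: sum(E_v) / sum(rho_v * V_v), per history."""
    mask = np.asarray(organ_mask, bool)
    if not mask.any():
        raise ValueError("organ mask is empty")
    mass = float((phantom.density[mask] * phantom.voxel_volume).sum())
    return float(tally.energy[mask].sum()) / mass / tally.n_histories


def ctdivol_from_scheme(
    scheme: TCMScheme, scanner: ScannerModel, effective_mas: bool = True
) -> float:
    """CTDIvol (mGy) = ctdi_per_mas x scan-averaged per-rotation mAs.

    With ``effective_mas=True`` (default) the scanner constant is treated as
    quoted per effective mAs (mAs / pitch), the convention consistent with a
    pitch-0.6 protocol page; set False for per-actual-mAs constants.
    """
    if scheme.current.size == 0:
        raise ValueError("empty scheme")
    mean_mas = float(scheme.rotation_mean.mean()) * scanner.rotation_time
    if effective_mas:
        mean_mas /= scanner.pitch
    return scanner.ctdi_per_mas * mean_mas


def normalized_dose(dose: float, ctdivol: float) -> float:
    """nD = D / CTDIvol (dimensionless when D is in CTDIvol-consistent units)."""
    if ctdivol <= 0:
        raise ValueError("ctdivol must be positive")
    return dose / ctdivol


def delta_percent(nd_ob: float, nd_at: float) -> float:
    """Within-patient percent difference of normalized dose, relative to ATCM."""
    if nd_at <= 0:
        raise ValueError("ATCM normalized dose must be positive")
    return 100.0 * (nd_ob - nd_at) / nd_at


def round_half_away(x: float) -> int:
    """Round half away from zero (the printed-table convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))
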