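"""Monte Carlo photon transport through voxel phantoms on a helical CT orbit.

Kerma-approximation transport: photons only, with photoelectric absorption,
incoherent (Klein--Nishina) scatter and optional coherent scatter; secondary
electron energy is deposited at the interaction site; histories terminate
below a 1 keV cutoff or on leaving the voxel grid.  Voxel traversal uses
Woodcock (delta) tracking against an energy-dependent majorant cross
section, which is unbiased in expectation with respect to exact ray tracing.

Histories are emitted along the helix z(alpha) = start_z + pitch *
collimation * alpha / (2*pi), weighted by the tube-current modulation weight
at their (z, theta) emission point and by the energy-dependent bowtie
transmission at their fan angle.  Tallies are accumulated in independent
batches for an empirical standard-error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import physics
from .phantoms import VoxelPhantom
from .source import SourceModel
from .tcm import TCMScheme, normalize_weights

__all__ = [
    "ScanGeometry",
    "DoseTally",
    "simulate_scan",
    "estimate_uncertainty",
    "primary_transmission",
    "simulate_ctdi_phantom",
]

ENERGY_CUTOFF_KEV = 1.0


@dataclass(frozen=True)
class ScanGeometry:
    """Helical scan definition (lengths in cm, time in s)."""

    start_z: float
    end_z: float
    pitch: float = 0.6
    collimation: float = 5.76
    rotation_time: float = 0.5
    source_radius: float = 59.5
    start_angle: float = 0.0
    n_histories: int = 2_000_000
    seed: int = 0
    n_batches: int = 10

    def __post_init__(self):
        if self.end_z <= self.start_z:
            raise ValueError("end_z must exceed start_z")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches")


@dataclass(frozen=True)
class DoseTally:
    """Per-voxel deposited energy (keV x history weight) with batch copies."""

    energy: np.ndarray  # (nz, ny, nx), sum over batches
    batch_tallies: np.ndarray  # (n_batches, nz, ny, nx)
    n_histories: int
    emitted_energy: float  # total keV x weight emitted

    @property
    def per_history(self) -> np.ndarray:
        return self.energy / self.n_histories


# ---------------------------------------------------------------- RNG ----
@njit(inline="always")
def _rng_next(state):
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    state[0] = s
    return np.float64((s * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(inline="always")
def _seed_state(seed, stream):
    # splitmix64 of (seed, stream) -> non-zero xorshift state
    z = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(stream + 1)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0xDEADBEEF)
    return z


@njit(inline="always")
def _mu_lookup(table, mat, ie, frac):
    return table[mat, ie] * (1.0 - frac) + table[mat, ie + 1] * frac


@njit(inline="always")
def _energy_index(e, ln_e0, inv_dln, n_e):
    f = (np.log(e) - ln_e0) * inv_dln
    if f < 0.0:
        f = 0.0
    if f > n_e - 1.001:
        f = n_e - 1.001
    ie = int(f)
    return ie, f - ie


@njit(inline="always")
def _rotate_direction(ux, uy, uz, cos_t, phi):
    """Rotate direction by polar angle theta (cosine given) and azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
        vy = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
        vz = -sin_t * denom * cp + uz * cos_t
    else:
        sign = 1.0 if uz > 0 else -1.0
        vx = sin_t * cp
        vy = sin_t * sp
        vz = sign * cos_t
    norm = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx * norm, vy * norm, vz * norm


@njit(inline="always")
def _sample_kn_cos(state, alpha):
    """Rejection sampling of the Klein--Nishina scattering-angle cosine."""
    while True:
        c = 2.0 * _rng_next(state) - 1.0
        r = 1.0 / (1.0 + alpha * (1.0 - c))
        f = r + r * r * r - r * r * (1.0 - c * c)
        if 2.0 * _rng_next(state) <= f:
            return c


@njit(inline="always")
def _sample_thomson_cos(state):
    while True:
        c = 2.0 * _rng_next(state) - 1.0
        if 2.0 * _rng_next(state) <= 1.0 + c * c:
            return c


@njit
def _transport_kernel(
    mat,
    rho,
    dz,
    dy,
    dx,
    ln_e0,
    inv_dln,
    mu_pe,
    mu_inc,
    mu_coh,
    mu_tot,
    majorant,
    spec_cdf,
    spec_e,
    spec_bowtie_mu,
    tau0k,
    fan_max,
    w_z0,
    w_dz,
    weights,
    start_z,
    travel_per_rad,
    alpha_total,
    start_angle,
    src_radius,
    coll,
    n_hist,
    seed,
    stream_offset,
    tally,
    coherent_on,
):
    nz, ny, nx = mat.shape
    n_e = majorant.shape[0]
    n_wpos, n_wang = weights.shape
    x_min = -nx * dx / 2.0
    y_min = -ny * dy / 2.0
    z_min = 0.0
    x_max = -x_min
    y_max = -y_min
    z_max = nz * dz
    two_pi = 2.0 * np.pi
    emitted = 0.0
    state = np.empty(1, dtype=np.uint64)
    state[0] = _seed_state(seed, stream_offset)

    for _ in range(n_hist):
        # --- emission point on the helix
        alpha = _rng_next(state) * alpha_total
        zs = start_z + travel_per_rad * alpha
        theta = (start_angle + alpha) % two_pi
        sx = src_radius * np.sin(theta)
        sy = -src_radius * np.cos(theta)

        # --- TCM weight at (z, theta): nearest grid cell
        ip = int((zs - w_z0) / w_dz + 0.5)
        if ip < 0:
            ip = 0
        if ip >= n_wpos:
            ip = n_wpos - 1
        ia = int(theta / two_pi * n_wang + 0.5) % n_wang
        w = weights[ip, ia]

        # --- energy from the spectrum
        u = _rng_next(state)
        k = np.searchsorted(spec_cdf, u)
        if k >= spec_e.shape[0]:
            k = spec_e.shape[0] - 1
        e = spec_e[k]

        # --- fan angle, bowtie weight, collimation
        phi = (2.0 * _rng_next(state) - 1.0) * fan_max
        tau = tau0k * (1.0 / np.cos(phi) - 1.0)
        w *= np.exp(-spec_bowtie_mu[k] * tau)
        dzoff = (_rng_next(state) - 0.5) * coll

        # direction: central ray rotated by phi in-plane, tilted by dzoff/R
        d0x = -np.sin(theta)
        d0y = np.cos(theta)
        cp = np.cos(phi)
        sp = np.sin(phi)
        ux = d0x * cp - d0y * sp
        uy = d0x * sp + d0y * cp
        uz = dzoff / src_radius
        norm = 1.0 / np.sqrt(ux * ux + uy * uy + uz * uz)
        ux *= norm
        uy *= norm
        uz *= norm

        emitted += e * w
        px, py, pz = sx, sy, zs

        # --- advance to the grid bounding box
        t0 = 0.0
        t1 = 1.0e30
        inside = True
        for axis in range(3):
            if axis == 0:
                p, d, lo_b, hi_b = px, ux, x_min, x_max
            elif axis == 1:
                p, d, lo_b, hi_b = py, uy, y_min, y_max
            else:
                p, d, lo_b, hi_b = pz, uz, z_min, z_max
            if abs(d) < 1.0e-12:
                if p < lo_b or p > hi_b:
                    inside = False
                    break
            else:
                ta = (lo_b - p) / d
                tb = (hi_b - p) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
        if not inside or t1 <= t0:
            continue
        px += ux * (t0 + 1.0e-6)
        py += uy * (t0 + 1.0e-6)
        pz += uz * (t0 + 1.0e-6)

        ie, fr = _energy_index(e, ln_e0, inv_dln, n_e)
        mu_maj = max(majorant[ie], majorant[ie + 1])

        # --- Woodcock tracking
        alive = True
        while alive:
            step = -np.log(_rng_next(state)) / mu_maj
            px += ux * step
            py += uy * step
            pz += uz * step
            iix = int((px - x_min) / dx)
            iiy = int((py - y_min) / dy)
            iiz = int((pz - z_min) / dz)
            if iix < 0 or iix >= nx or iiy < 0 or iiy >= ny or iiz < 0 or iiz >= nz:
                break  # photon left the grid
            m = mat[iiz, iiy, iix]
            r = rho[iiz, iiy, iix]
            mt = r * _mu_lookup(mu_tot, m, ie, fr)
            if _rng_next(state) * mu_maj > mt:
                continue  # virtual collision
            # real collision: choose the interaction
            pe = r * _mu_lookup(mu_pe, m, ie, fr)
            inc = r * _mu_lookup(mu_inc, m, ie, fr)
            xi = _rng_next(state) * mt
            if xi < pe:
                tally[iiz, iiy, iix] += e * w
                alive = False
            elif xi < pe + inc or not coherent_on:
                a = e / 510.99895
                c = _sample_kn_cos(state, a)
                e_new = e / (1.0 + a * (1.0 - c))
                tally[iiz, iiy, iix] += (e - e_new) * w
                if e_new < ENERGY_CUTOFF_KEV:
                    tally[iiz, iiy, iix] += e_new * w
                    alive = False
                else:
                    e = e_new
                    az = two_pi * _rng_next(state)
                    ux, uy, uz = _rotate_direction(ux, uy, uz, c, az)
                    ie, fr = _energy_index(e, ln_e0, inv_dln, n_e)
                    mu_maj = max(majorant[ie], majorant[ie + 1])
            else:
                c = _sample_thomson_cos(state)
                az = two_pi * _rng_next(state)
                ux, uy, uz = _rotate_direction(ux, uy, uz, c, az)
    return emitted


def _mu_tables():
    energies, pe, inc, coh = physics.build_mu_tables()
    return energies, pe, inc, coh, pe + inc + coh


def _phantom_majorant(phantom: VoxelPhantom, mu_tot: np.ndarray) -> np.ndarray:
    """Energy-wise majorant: max over material families present of
    mu/rho * (max density of that family in this phantom)."""
    maj = np.zeros(mu_tot.shape[1])
    for m in range(physics.N_MATERIALS):
        sel = phantom.material_id == m
        if np.any(sel):
            maj = np.maximum(maj, mu_tot[m] * phantom.density[sel].max())
    return maj


def _coerce_weights(scheme_weights, positions, angles):
    if isinstance(scheme_weights, TCMScheme):
        w = normalize_weights(scheme_weights)
        return scheme_weights.table_positions, scheme_weights.angle_bins, w
    w = np.asarray(scheme_weights, float)
    if positions is None or angles is None:
        raise ValueError("positions and angles required with a raw weight grid")
    return np.asarray(positions, float), np.asarray(angles, float), w


def simulate_scan(
    phantom: VoxelPhantom,
    scheme_weights,
    spec: SourceModel,
    geom: ScanGeometry,
    positions=None,
    angles=None,
    coherent: bool = True,
) -> DoseTally:
    """Run the helical MC scan and return the per-voxel energy tally.

    ``scheme_weights`` is either a TCMScheme (normalized internally) or a
    (position x angle) weight grid in (0, 1] with explicit ``positions`` (cm)
    and ``angles`` (radians).
    """
    wpos, wang, weights = _coerce_weights(scheme_weights, positions, angles)
    if weights.max() > 1.0 + 1e-12 or weights.min() <= 0.0:
        raise ValueError("weights must lie in (0, 1]")
    if wpos[0] > geom.start_z + 1e-9 or wpos[-1] < geom.end_z - 1e-9:
        # a nearest-neighbour lookup outside the grid would silently clamp
        pad = (wpos[1] - wpos[0]) if len(wpos) > 1 else geom.collimation
        if geom.start_z < wpos[0] - pad or geom.end_z > wpos[-1] + pad:
            raise ValueError("TCM scheme does not cover the scan range")

    energies, pe, inc, coh, tot = _mu_tables()
    majorant = _phantom_majorant(phantom, tot)
    ln_e0 = np.log(energies[0])
    inv_dln = 1.0 / np.log(energies[1] / energies[0])

    cdf = np.cumsum(spec.fluence)
    cdf /= cdf[-1]
    spec_bowtie_mu = physics.mu_aluminum(spec.energies_kev)

    travel_per_rad = geom.pitch * geom.collimation / (2.0 * np.pi)
    alpha_total = (geom.end_z - geom.start_z) / travel_per_rad

    dzv, dyv, dxv = phantom.voxel_size
    nz, ny, nx = phantom.material_id.shape
    n_b = geom.n_batches
    per_batch = np.full(n_b, geom.n_histories // n_b, int)
    per_batch[: geom.n_histories % n_b] += 1

    batch_tallies = np.zeros((n_b, nz, ny, nx))
    emitted = 0.0
    mat = np.ascontiguousarray(phantom.material_id)
    rho = np.ascontiguousarray(phantom.density)
    for b in range(n_b):
        emitted += _transport_kernel(
            mat,
            rho,
            dzv,
            dyv,
            dxv,
            ln_e0,
            inv_dln,
            pe,
            inc,
            coh,
            tot,
            majorant,
            cdf,
            spec.energies_kev,
            spec_bowtie_mu,
            spec.bowtie_tau0 * spec.bowtie_k,
            spec.fan_angle_max,
            wpos[0],
            wpos[1] - wpos[0] if len(wpos) > 1 else 1.0,
            weights,
            geom.start_z,
            travel_per_rad,
            alpha_total,
            geom.start_angle,
            geom.source_radius,
            geom.collimation,
            int(per_batch[b]),
            geom.seed,
            b,
            batch_tallies[b],
            coherent,
        )
    return DoseTally(
        energy=batch_tallies.sum(axis=0),
        batch_tallies=batch_tallies,
        n_histories=int(geom.n_histories),
        emitted_energy=float(emitted),
    )


def estimate_uncertainty(tally: DoseTally, region_mask: np.ndarray) -> float:
    """Relative standard error of the region-summed dose from batch spread."""
    n_b = tally.batch_tallies.shape[0]
    if n_b < 2:
        raise ValueError("need at least 2 batches")
    mask = np.asarray(region_mask, bool)
    sums = tally.batch_tallies[:, mask].sum(axis=1)
    mean = sums.mean()
    if mean == 0:
        raise ValueError("region received zero dose")
    se = sums.std(ddof=1) / np.sqrt(n_b)
    return float(se / mean)


@njit
def _slab_kernel(thickness, mu_real, mu_maj, n, seed):
    transmitted = 0
    state = np.empty(1, dtype=np.uint64)
    state[0] = _seed_state(seed, 7919)
    for _ in range(n):
        pos = 0.0
        while True:
            pos += -np.log(_rng_next(state)) / mu_maj
            if pos >= thickness:
                transmitted += 1
                break
            if _rng_next(state) * mu_maj <= mu_real:
                break
    return transmitted


def primary_transmission(
    material: int,
    density: float,
    thickness_cm: float,
    energy_kev: float,
    n_histories: int = 1_000_000,
    seed: int = 0,
    majorant_factor: float = 1.5,
):
    """Uncollided fraction through a homogeneous slab (Woodcock-tracked).

    Returns (estimate, standard error); the analytic value is
    exp(-mu * thickness) for the same cross-section tables.
    """
    mu_real = density * float(physics.mu_rho_total(material, energy_kev))
    k = _slab_kernel(thickness_cm, mu_real, mu_real * majorant_factor, n_histories, seed)
    p = k / n_histories
    se = np.sqrt(max(p * (1.0 - p), 1e-300) / n_histories)
    return p, se


def build_ctdi_phantom(length_cm: float = 20.0, pixel_cm: float = 0.5, dz_cm: float = 1.0):
    """Standard 32-cm PMMA dose-index cylinder with centre + 4 peripheral
    100-mm probe masks (peripheral axes 1 cm below the surface)."""
    radius = 16.0
    nxy = int(np.ceil(2 * (radius + 1.0) / pixel_cm))
    nz = int(np.ceil(length_cm / dz_cm))
    y, x = np.meshgrid(
        (np.arange(nxy) - (nxy - 1) / 2) * pixel_cm,
        (np.arange(nxy) - (nxy - 1) / 2) * pixel_cm,
        indexing="ij",
    )
    rr = np.sqrt(x**2 + y**2)
    body = rr <= radius
    mat = np.where(body, physics.PMMA, physics.AIR).astype(np.uint8)
    rho = np.where(body, 1.19, 0.0012)
    mat = np.broadcast_to(mat, (nz, nxy, nxy)).copy()
    rho = np.broadcast_to(rho, (nz, nxy, nxy)).copy()

    probe_len = 10.0
    z = (np.arange(nz) + 0.5) * dz_cm
    z_sel = np.abs(z - length_cm / 2.0) <= probe_len / 2.0
    probe_r = 1.0
    masks = {}
    centers = {
        "center": (0.0, 0.0),
        "anterior": (0.0, -15.0),
        "posterior": (0.0, 15.0),
        "left": (15.0, 0.0),
        "right": (-15.0, 0.0),
    }
    for name, (cx, cy) in centers.items():
        m2d = (x - cx) ** 2 + (y - cy) ** 2 <= probe_r**2
        m = np.zeros((nz, nxy, nxy), bool)
        m[z_sel] = m2d
        masks[name] = m
    return VoxelPhantom(
        material_id=mat, density=rho, voxel_size=(dz_cm, pixel_cm, pixel_cm), organ_masks=masks
    )


def simulate_ctdi_phantom(
    spec: SourceModel, geom: ScanGeometry, scheme: TCMScheme, coherent: bool = True
) -> dict:
    """Dose-index validation scan of the 32-cm PMMA cylinder.

    Returns probe doses, the weighted dose index (1/3 centre + 2/3 mean
    periphery) and its pitch-corrected volume value, all per unit of the
    scheme's mean rotation mAs (relative units; the package carries no
    absolute mAs-to-fluence calibration).
    """
    phantom = build_ctdi_phantom(length_cm=geom.end_z - geom.start_z + 10.0)
    tally = simulate_scan(phantom, scheme, spec, geom, coherent=coherent)
    mean_mas = float(scheme.rotation_mean.mean() * geom.rotation_time)
    # history weights are I/I_max, so restore the scheme's current scale
    # before normalizing by its mAs
    peak = float(scheme.current.max())
    probes = {}
    for name in ("center", "anterior", "posterior", "left", "right"):
        mask = phantom.organ_masks[name]
        mass = (phantom.density[mask] * phantom.voxel_volume).sum()
        probes[name] = float(tally.energy[mask].sum() / mass / tally.n_histories) * peak
    periphery = np.mean([probes[k] for k in ("anterior", "posterior", "left", "right")])
    ctdi_w = probes["center"] / 3.0 + 2.0 * periphery / 3.0
    return {
        "probes_per_mas": {k: v / mean_mas for k, v in probes.items()},
        "ctdi_w_per_mas": ctdi_w / mean_mas,
        "ctdi_vol_per_mas": ctdi_w / mean_mas / geom.pitch,
        "tally": tally,
    }
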