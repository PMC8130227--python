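"""Monte Carlo transport engine: analytic, symmetry and statistical checks.

The heavier checks run at reduced history counts here; the acceptance suite
repeats them at the counts quoted there.
"""

import dataclasses

import numpy as np
import pytest

from tcmdose import physics
from tcmdose.tcm import TCMScheme
from tcmdose.transport import (
    DoseTally,
    ScanGeometry,
    estimate_uncertainty,
    primary_transmission,
    simulate_ctdi_phantom,
    simulate_scan,
)

from conftest import water_cylinder_phantom


def flat_weights(n_pos=16, n_ang=36, z_max=16.0, value=1.0):
    pos = np.linspace(0.0, z_max, n_pos)
    ang = np.arange(n_ang) * 2.0 * np.pi / n_ang
    return pos, ang, np.full((n_pos, n_ang), value)


class TestBeerLambert:
    def test_water_slab_uncollided_fraction(self):
        est, se = primary_transmission(physics.WATER, 1.0, 10.0, 60.0, 300_000, seed=2)
        exact = np.exp(-float(physics.mu_rho_total(physics.WATER, 60.0)) * 10.0)
        assert abs(est - exact) < 3.0 * se

    def test_reproducible(self):
        a, _ = primary_transmission(physics.WATER, 1.0, 5.0, 60.0, 50_000, seed=5)
        b, _ = primary_transmission(physics.WATER, 1.0, 5.0, 60.0, 50_000, seed=5)
        assert a == b


@pytest.fixture(scope="module")
def cylinder_run(force_source):
    vp = water_cylinder_phantom(diameter_cm=24.0, n_slices=12)
    pos, ang, w = flat_weights(z_max=12.0)
    geom = ScanGeometry(start_z=2.0, end_z=10.0, n_histories=150_000, seed=4, n_batches=6)
    tally = simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)
    return vp, geom, tally


@pytest.fixture(scope="module")
def ctdi_runs(force_source):
    theta = np.arange(12) * 2.0 * np.pi / 12.0
    z = np.linspace(0.0, 20.0, 8)
    flat = TCMScheme(z, theta, np.full((8, 12), 100.0), "file")
    from tcmdose.tcm import apply_obtcm

    ob = apply_obtcm(flat, 0.25, 120, compensate=True)
    geom = ScanGeometry(start_z=5.0, end_z=15.0, n_histories=250_000, seed=12, n_batches=5)
    return {
        "flat": simulate_ctdi_phantom(force_source, geom, flat),
        "double": simulate_ctdi_phantom(
            force_source, geom, TCMScheme(z, theta, np.full((8, 12), 200.0), "file")
        ),
        "obtcm": simulate_ctdi_phantom(force_source, geom, ob),
    }


class TestSimulateScan:
    def test_energy_conservation(self, cylinder_run):
        _, _, tally = cylinder_run
        assert 0.0 < tally.energy.sum() <= tally.emitted_energy

    def test_same_seed_identical_tallies(self, force_source):
        vp = water_cylinder_phantom(diameter_cm=20.0, n_slices=8)
        pos, ang, w = flat_weights(z_max=8.0)
        geom = ScanGeometry(start_z=2.0, end_z=6.0, n_histories=40_000, seed=9, n_batches=4)
        t1 = simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)
        t2 = simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)
        assert np.array_equal(t1.energy, t2.energy)

    def test_weight_linearity_exact(self, force_source):
        # halving every weight halves every voxel tally bit-exactly
        vp = water_cylinder_phantom(diameter_cm=20.0, n_slices=8)
        pos, ang, w1 = flat_weights(z_max=8.0, value=1.0)
        _, _, w2 = flat_weights(z_max=8.0, value=0.5)
        geom = ScanGeometry(start_z=2.0, end_z=6.0, n_histories=30_000, seed=3, n_batches=4)
        t1 = simulate_scan(vp, w1, force_source, geom, positions=pos, angles=ang)
        t2 = simulate_scan(vp, w2, force_source, geom, positions=pos, angles=ang)
        assert np.array_equal(t1.energy, 2.0 * t2.energy)

    def test_left_right_symmetry(self, female_phantom, force_source):
        # mirror-symmetrize the phantom so the only asymmetry is MC noise,
        # and scan a whole number of rotations so the azimuthal fluence is
        # uniform in aggregate
        nx = female_phantom.material_id.shape[2]
        half = nx // 2
        sym = dataclasses.replace(
            female_phantom,
            material_id=female_phantom.material_id.copy(),
            density=female_phantom.density.copy(),
        )
        sym.material_id[:, :, half:] = sym.material_id[:, :, :half][:, :, ::-1]
        sym.density[:, :, half:] = sym.density[:, :, :half][:, :, ::-1]
        lung = female_phantom.organ_masks["lung"].copy()
        lung[:, :, half:] = lung[:, :, :half][:, :, ::-1]
        left = lung.copy()
        left[:, :, :half] = False
        right = lung.copy()
        right[:, :, half:] = False
        pos, ang, w = flat_weights(z_max=16.0)
        travel = 0.6 * 5.76  # table travel per rotation
        geom = ScanGeometry(
            start_z=1.0, end_z=1.0 + 4 * travel, n_histories=400_000, seed=6, n_batches=8
        )
        tally = simulate_scan(sym, w, force_source, geom, positions=pos, angles=ang)
        dl = tally.energy[left].sum()
        dr = tally.energy[right].sum()
        sigma = np.hypot(
            estimate_uncertainty(tally, left) * dl, estimate_uncertainty(tally, right) * dr
        )
        assert abs(dl - dr) < 3.0 * sigma

    def test_invalid_weights_rejected(self, force_source):
        vp = water_cylinder_phantom(diameter_cm=20.0, n_slices=8)
        pos, ang, w = flat_weights(z_max=8.0, value=1.5)
        geom = ScanGeometry(start_z=2.0, end_z=6.0, n_histories=1000, seed=0, n_batches=2)
        with pytest.raises(ValueError, match="weights"):
            simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)

    def test_scheme_must_cover_scan(self, force_source):
        vp = water_cylinder_phantom(diameter_cm=20.0, n_slices=8)
        pos, ang, w = flat_weights(n_pos=4, z_max=3.0)
        geom = ScanGeometry(start_z=0.5, end_z=7.5, n_histories=1000, seed=0, n_batches=2)
        with pytest.raises(ValueError, match="cover"):
            simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)


class TestUncertainty:
    def test_quarter_histories_doubles_se(self, force_source):
        vp = water_cylinder_phantom(diameter_cm=20.0, n_slices=8)
        pos, ang, w = flat_weights(z_max=8.0)
        core = np.zeros(vp.material_id.shape, bool)
        core[3:5, 20:28, 20:28] = True
        ses = []
        for n in (50_000, 200_000):
            geom = ScanGeometry(start_z=2.0, end_z=6.0, n_histories=n, seed=8, n_batches=10)
            t = simulate_scan(vp, w, force_source, geom, positions=pos, angles=ang)
            ses.append(estimate_uncertainty(t, core))
        ratio = ses[0] / ses[1]
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3  # 1/sqrt(N) within 30%

    def test_identical_batches_zero_se(self):
        batch = np.ones((4, 2, 2, 2))
        tally = DoseTally(batch.sum(axis=0), batch, 100, 100.0)
        assert estimate_uncertainty(tally, np.ones((2, 2, 2), bool)) == 0.0

    def test_zero_dose_region_rejected(self):
        batch = np.zeros((4, 2, 2, 2))
        tally = DoseTally(batch.sum(axis=0), batch, 100, 100.0)
        with pytest.raises(ValueError):
            estimate_uncertainty(tally, np.ones((2, 2, 2), bool))


class TestCtdiPhantom:
    def test_per_mas_invariant_to_output_level(self, ctdi_runs):
        # doubling every current leaves the per-mAs index unchanged
        # (identical weights => identical histories)
        assert ctdi_runs["flat"]["ctdi_vol_per_mas"] == pytest.approx(
            ctdi_runs["double"]["ctdi_vol_per_mas"], rel=1e-12
        )

    def test_peripheral_symmetry_flat_scheme(self, ctdi_runs):
        p = ctdi_runs["flat"]["probes_per_mas"]
        vals = [p["anterior"], p["posterior"], p["left"], p["right"]]
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.10

    def test_obtcm_shifts_dose_posteriorly(self, ctdi_runs):
        p = ctdi_runs["obtcm"]["probes_per_mas"]
        assert p["anterior"] < p["posterior"]


class TestGeometryValidation:
    def test_bad_scan_range(self):
        with pytest.raises(ValueError):
            ScanGeometry(start_z=5.0, end_z=5.0)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            ScanGeometry(start_z=0.0, end_z=5.0, n_batches=1)
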