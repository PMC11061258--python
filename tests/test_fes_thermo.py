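"""Metadynamics post-processing: HILLS, FES, projections, kappa, DG0, DDG0."""
import numpy as np
import pytest
from scipy import integrate

from helimem import fes_thermo as ft
from helimem import synthetic_data as sd
from helimem._constants import KB_KJ_PER_MOL_K
from helimem.core import CVAxis, FESGrid, HillsRecord, InputError, PMFProfile, ValidationError

KT300 = KB_KJ_PER_MOL_K * 300.0
BETA300 = 1.0 / KT300


def simple_hills(n, rng, ncv=2, sigma=(0.2, 0.1), ranges=((0, 8), (-1, 1)),
                 gamma=50.0):
    centers = np.column_stack([rng.uniform(*ranges[d], n) for d in range(ncv)])
    return HillsRecord(
        ["z", "cos_tilt"][:ncv], np.arange(n, dtype=float), centers,
        np.tile(np.asarray(sigma[:ncv]), (n, 1)), rng.uniform(0.5, 2.2, n),
        gamma, np.zeros(n, dtype=int),
    )


class TestHillsIO:
    def test_empty_file_set_gives_empty_record(self):
        rec = ft.read_hills([])
        assert rec.n_hills == 0

    def test_two_walkers_merge_sorted(self, tmp_path, rng):
        rec = simple_hills(20, rng)
        rec.walker_ids = np.arange(20) % 2
        paths = []
        for w in (0, 1):
            p = tmp_path / f"HILLS.{w}"
            ft.write_hills(rec, p, walker_id=w)
            paths.append(p)
        merged = ft.read_hills(paths)
        assert merged.n_hills == 20
        assert np.all(np.diff(merged.times) >= 0)
        assert set(merged.walker_ids.tolist()) == {0, 1}

    def test_roundtrip_preserves_fields(self, tmp_path, rng):
        rec = simple_hills(15, rng)
        path = tmp_path / "HILLS"
        ft.write_hills(rec, path)
        back = ft.read_hills([path])
        assert back.cv_names == rec.cv_names
        assert np.allclose(back.centers, rec.centers)
        assert np.allclose(back.sigmas, rec.sigmas)
        assert np.allclose(back.heights, rec.heights)
        assert back.bias_factor == rec.bias_factor

    def test_inconsistent_cv_sets_rejected(self, tmp_path, rng):
        a = tmp_path / "a"
        a.write_text("#! FIELDS time z sigma_z height biasf\n0 1 0.1 2 50\n")
        b = tmp_path / "b"
        b.write_text("#! FIELDS time spin sigma_spin height biasf\n0 1 0.1 2 50\n")
        with pytest.raises(InputError, match="CV set"):
            ft.read_hills([a, b])

    def test_negative_width_rejected(self, tmp_path):
        p = tmp_path / "bad"
        p.write_text("#! FIELDS time z sigma_z height biasf\n0 1 -0.1 2 50\n")
        with pytest.raises(InputError, match="negative"):
            ft.read_hills([p])


class TestReconstructFES:
    def test_no_hills_gives_flat_zero(self):
        rec = ft.read_hills([])
        fes = ft.reconstruct_fes(rec, {"z": (0, 8, 50)})
        assert np.all(fes.values == 0.0)

    def test_single_gaussian_well_depth(self):
        gamma, h = 50.0, 2.2
        rec = HillsRecord(["z"], [0.0], [[4.0]], [[0.3]], [h], gamma, [0])
        fes = ft.reconstruct_fes(rec, {"z": (0, 8, 801)})
        # far field sits at +gamma/(gamma-1)*h after the min-to-zero shift
        depth = fes.values.max() - fes.values.min()
        assert depth == pytest.approx(gamma / (gamma - 1) * h, rel=1e-6)
        assert fes.values[np.argmin(np.abs(np.linspace(0, 8, 801) - 4.0))] == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        rec = simple_hills(300, rng)
        fes = ft.reconstruct_fes(rec, {"z": (-2, 10, 80), "cos_tilt": (-1.5, 1.5, 60)})
        zv = np.linspace(-2, 10, 80)
        cv = np.linspace(-1.5, 1.5, 60)
        bias = np.zeros((80, 60))
        for i in range(rec.n_hills):
            dz = (zv[:, None] - rec.centers[i, 0]) / rec.sigmas[i, 0]
            dc = (cv[None, :] - rec.centers[i, 1]) / rec.sigmas[i, 1]
            bias += rec.heights[i] * np.exp(-0.5 * (dz**2 + dc**2))
        oracle = -(50.0 / 49.0) * bias
        oracle -= oracle.min()
        assert np.abs(oracle - fes.values).max() < 1e-9

    def test_periodic_axis_uses_minimum_image(self):
        # a hill near the edge of a periodic spin axis wraps around: the
        # reconstruction must match a brute-force sum over periodic images
        period = 2 * np.pi
        rec = HillsRecord(["spin"], [0.0], [[0.1]], [[0.3]], [2.0], 50.0, [0])
        fes = ft.reconstruct_fes(rec, {"spin": (0, period, 100, period)})
        grid = np.linspace(0, period, 100)
        bias = np.zeros(100)
        for image in (-1, 0, 1):
            bias += 2.0 * np.exp(-0.5 * ((grid - 0.1 - image * period) / 0.3) ** 2)
        oracle = -(50.0 / 49.0) * bias
        oracle -= oracle.min()
        assert np.abs(fes.values - oracle).max() < 1e-9

    def test_bad_bias_factor_rejected(self, rng):
        rec = simple_hills(5, rng, gamma=0.5)
        with pytest.raises(ValidationError):
            ft.reconstruct_fes(rec, {"z": (0, 8, 50), "cos_tilt": (-1, 1, 20)})

    def test_uncovered_centers_warn(self, rng):
        rec = simple_hills(5, rng)
        with pytest.warns(UserWarning, match="truncated"):
            ft.reconstruct_fes(rec, {"z": (3, 4, 20), "cos_tilt": (-1, 1, 10)})


class TestProjection:
    def test_tilt_independent_surface_projects_to_slice(self):
        z = np.linspace(0, 8, 200)
        c = np.linspace(-1, 1, 41)
        f = -20.0 * np.exp(-((z - 1.5) ** 2) / 0.18)
        fes = FESGrid([CVAxis("z", z, unit="nm"), CVAxis("cos_tilt", c)],
                      np.repeat(f[:, None], 41, axis=1))
        pmf = ft.project_to_1d(fes, "z")
        diff = pmf.values - (f - f.min())
        assert np.ptp(diff) < 1e-9  # equal up to an additive constant

    def test_separable_surface_quadrature_oracle(self):
        z = np.linspace(0, 8, 400)
        c = np.linspace(-1, 1, 201)
        fz = -15.0 * np.exp(-((z - 2.0) ** 2) / 0.5)
        gc = 3.0 * c**2
        fes = FESGrid([CVAxis("z", z, unit="nm"), CVAxis("cos_tilt", c)],
                      fz[:, None] + gc[None, :])
        pmf = ft.project_to_1d(fes, "z", temperature=300.0)
        const, _ = integrate.quad(lambda u: np.exp(-BETA300 * 3.0 * u**2), -1, 1)
        expected = fz - np.log(const) / BETA300
        diff = pmf.values - (expected - expected.min())
        assert np.ptp(diff) < 1e-4  # trapezoid vs adaptive quadrature in g

    def test_flat_surface_projects_to_zero(self):
        fes = FESGrid([CVAxis("z", np.linspace(0, 8, 50)),
                       CVAxis("cos_tilt", np.linspace(-1, 1, 21))],
                      np.zeros((50, 21)))
        pmf = ft.project_to_1d(fes, "z")
        assert np.allclose(pmf.values, 0.0, atol=1e-12)


class TestKappa:
    def test_flat_surface_kappa_is_one(self):
        fes, kex = sd.make_analytic_fes("flat", {}, n_z=101, n_cos=11)
        res = ft.kappa_from_2d(fes, lam=4.0)
        assert res.kappa == pytest.approx(1.0, rel=1e-12)
        assert kex(4.0) == 1.0

    def test_square_well_closed_form_2d_and_1d(self):
        fes, kex = sd.make_analytic_fes(
            "square_well", {"eps": 10.0, "z1": 1.0, "z2": 2.0, "ramp": 0.4},
            n_z=32001, n_cos=11)
        lam = 4.0
        r2 = ft.kappa_from_2d(fes, lam)
        r1 = ft.kappa_from_1d(ft.project_to_1d(fes, "z"), lam)
        assert r2.kappa == pytest.approx(kex(lam), rel=1e-6)
        assert r1.kappa == pytest.approx(kex(lam), rel=1e-6)

    def test_tilted_well_matches_quadrature(self):
        # sharp slab edges limit the trapezoid to O(h) there; the tolerance
        # reflects the grid actually used
        fes, kex = sd.make_analytic_fes(
            "tilted_well", {"eps": 6.0, "z1": 1.0, "z2": 2.0},
            n_z=16001, n_cos=401)
        res = ft.kappa_from_2d(fes, 4.0)
        assert res.kappa == pytest.approx(kex(4.0), rel=5e-4)

    def test_projection_consistency_2d_vs_1d(self):
        z = np.linspace(0, 8, 1500)
        c = np.linspace(-1, 1, 101)
        w = -18.0 * np.exp(-((z[:, None] - 1.8) ** 2) / 0.3) * (1.0 + 0.4 * c[None, :])
        fes = FESGrid([CVAxis("z", z, unit="nm"), CVAxis("cos_tilt", c)], w)
        lam = 4.5
        k2 = ft.kappa_from_2d(fes, lam).kappa
        k1 = ft.kappa_from_1d(ft.project_to_1d(fes, "z"), lam).kappa
        assert k2 == pytest.approx(k1, rel=1e-6)

    def test_constant_offset_behaviour(self):
        fes, _ = sd.make_analytic_fes(
            "square_well", {"eps": 8.0, "z1": 1.0, "z2": 2.0, "ramp": 0.2},
            n_z=2001, n_cos=11)
        shift = 5.0
        shifted = FESGrid(fes.axes, fes.values + shift, fes.temperature)
        lam = 4.0
        base = ft.kappa_from_2d(fes, lam, anchor=False).kappa
        off = ft.kappa_from_2d(shifted, lam, anchor=False).kappa
        assert off == pytest.approx(base * np.exp(-BETA300 * shift), rel=1e-9)
        anchored = ft.kappa_from_2d(shifted, lam, anchor=True).kappa
        assert anchored == pytest.approx(ft.kappa_from_2d(fes, lam).kappa, rel=1e-12)

    def test_grid_refinement_invariance(self):
        lam, vals = 4.0, []
        for n_z in (2001, 4001):
            fes, _ = sd.make_analytic_fes(
                "harmonic_well", {"eps": 8.0, "k": 50.0, "z0": 1.5},
                n_z=n_z, n_cos=5)
            vals.append(ft.kappa_from_2d(fes, lam).kappa)
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-4

    def test_lambda_outside_grid_rejected(self):
        fes, _ = sd.make_analytic_fes("flat", {}, n_z=51, n_cos=5)
        with pytest.raises(ValidationError):
            ft.kappa_from_2d(fes, lam=20.0)


class TestStandardState:
    def test_default_v0_matches_avogadro(self):
        import scipy.constants as sc
        v0_nm3 = 1e27 / (sc.N_A * 1e3)  # volume per molecule at 1 mol/L
        from helimem._constants import DEFAULT_V0_NM3
        assert DEFAULT_V0_NM3 == pytest.approx(v0_nm3, rel=5e-4)

    def test_kappa_one_lambda_cuberoot_v0_gives_zero_dg(self):
        lam = 1.660 ** (1.0 / 3.0)
        res = ft._bare_result(1.0, lam, 300.0, "eq_1d")
        out = ft.standard_state(res, V0=1.660)
        assert out.kappa0 == pytest.approx(1.0, rel=1e-12)
        assert out.dG0 == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_example(self):
        res = ft.standard_state(ft._bare_result(100.0, 3.0, 300.0, "eq_1d"), V0=1.660)
        kappa0 = 100.0 * 3.0 / 1.660 ** (1 / 3)
        expected = -0.0083145 * 300.0 * np.log(kappa0)
        assert out_close(res.dG0, expected)

    def test_nonpositive_inputs_rejected(self):
        res = ft._bare_result(1.0, 1.0, 300.0, "eq_1d")
        with pytest.raises(ValidationError):
            ft.standard_state(res, V0=-1.0)


def out_close(a, b, tol=1e-9):
    return abs(a - b) < tol


class TestTransfer:
    def _result(self, dg_target):
        # invert dG0 = -kT ln(kappa0) with lam = V0^(1/3) so kappa0 = kappa
        kappa = np.exp(-dg_target * BETA300)
        return ft.standard_state(
            ft._bare_result(kappa, 1.660 ** (1 / 3), 300.0, "eq_1d"), 1.660)

    def test_identical_results_give_zero(self):
        r = self._result(-30.0)
        assert ft.transfer_ddg(r, r).ddG0 == pytest.approx(0.0, abs=1e-9)

    def test_worked_example(self):
        rm, rc = self._result(-30.0), self._result(-50.0)
        assert ft.transfer_ddg(rm, rc).ddG0 == pytest.approx(-20.0, abs=1e-9)

    def test_antisymmetry(self):
        rm, rc = self._result(-31.7), self._result(-44.2)
        assert ft.transfer_ddg(rm, rc).ddG0 == -ft.transfer_ddg(rc, rm).ddG0

    def test_common_pmf_offset_cancels(self):
        z = np.linspace(0, 8, 2001)
        well = -12.0 * np.exp(-((z - 1.5) ** 2) / 0.25)
        deeper = -20.0 * np.exp(-((z - 1.5) ** 2) / 0.25)
        lam = 4.0
        def ddg(offset):
            pm = PMFProfile("z", z, well + offset)
            pc = PMFProfile("z", z, deeper + offset)
            return ft.transfer_ddg(ft.kappa_from_1d(pm, lam),
                                   ft.kappa_from_1d(pc, lam)).ddG0
        assert ddg(0.0) == pytest.approx(ddg(7.3), abs=1e-9)

    def test_mismatched_temperature_rejected(self):
        rm = self._result(-30.0)
        rc = ft.standard_state(
            ft._bare_result(2.0, 1.660 ** (1 / 3), 310.0, "eq_1d"), 1.660)
        with pytest.raises(ValidationError):
            ft.transfer_ddg(rm, rc)


class TestChooseLambda:
    def test_flat_profile_gives_lower_edge(self):
        z = np.linspace(0.5, 8, 100)
        lam = ft.choose_lambda(PMFProfile("z", z, np.zeros(100)))
        assert lam == pytest.approx(0.5)

    def test_square_well_edge_detected(self):
        z = np.linspace(0, 8, 801)
        w = np.where((z >= 1.0) & (z <= 2.0), -10.0, 0.0)
        lam = ft.choose_lambda(PMFProfile("z", z, w))
        assert 2.0 < lam <= 2.0 + 2 * 0.01

    def test_decaying_profile_crossing(self):
        z = np.linspace(0, 8, 1601)
        thr = 0.5 * KT300
        w = -10.0 * np.exp(-z)  # |W| = thr at z* = ln(10/thr)
        z_star = np.log(10.0 / thr)
        lam = ft.choose_lambda(PMFProfile("z", z, w))
        assert abs(lam - z_star) <= 0.005 + 1e-12

    def test_no_plateau_rejected(self):
        z = np.linspace(0, 8, 100)
        with pytest.raises(ValidationError, match="plateau"):
            ft.choose_lambda(PMFProfile("z", z, -10.0 * np.ones(100)))


class TestConvergenceAndWalls:
    def test_identical_profiles_zero_uncertainty(self):
        z = np.linspace(0, 8, 50)
        profs = [PMFProfile("z", z, np.sin(z)) for _ in range(10)]
        sig = ft.convergence_blocks(profs, trailing_fraction=0.3)
        assert np.allclose(sig, 0.0)

    def test_known_noise_recovered(self, rng):
        z = np.linspace(0, 8, 40)
        sigma_true = 0.7
        profs = [PMFProfile("z", z, rng.normal(0, sigma_true, 40))
                 for _ in range(60)]
        sig = ft.convergence_blocks(profs, trailing_fraction=1.0)
        assert np.mean(sig) == pytest.approx(sigma_true, rel=0.15)

    def test_too_few_trailing_profiles_rejected(self):
        z = np.linspace(0, 8, 10)
        profs = [PMFProfile("z", z, np.zeros(10))] * 4
        with pytest.raises(ValidationError):
            ft.convergence_blocks(profs, trailing_fraction=0.3)

    def test_dg0_uncertainty_zero_for_identical_profiles(self):
        z = np.linspace(0, 8, 400)
        w = -10.0 * np.exp(-((z - 1.5) ** 2) / 0.25)
        profs = [PMFProfile("z", z, w)] * 10
        assert ft.dg0_uncertainty(profs, lam=4.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("z, expected", [
        (4.0, 0.0), (0.0, 0.0), (8.0, 0.0),
        (8.1, 0.5 * 50000 * 0.01), (-0.2, 0.5 * 50000 * 0.04),
    ])
    def test_wall_bias_values(self, z, expected):
        assert ft.wall_bias(z) == pytest.approx(expected, rel=1e-9, abs=1e-12)
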