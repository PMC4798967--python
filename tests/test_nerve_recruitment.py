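import math

import numpy as np
import pytest

import neurotact.nerve_recruitment as nr
from neurotact.nerve_recruitment import (
    AxonParams,
    ElectrodeModel,
    Fascicle,
    NerveModel,
    RecruitmentCurve,
    StimPulse,
    TissueConductivities,
    axon_response,
    compare_devices,
    enumerate_simulation_plan,
    extracellular_potential,
    fiber_threshold,
    perineurium_crossings,
    sample_population,
)
from neurotact.nerve_recruitment import _node_phi


COND = TissueConductivities()


class TestPotentialField:
    def test_isotropic_limit_closed_form(self):
        sigma = 0.5
        cond = TissueConductivities(
            endoneurium=(sigma, sigma, sigma + 1e-12),
            perineurium=880e-6,
            epineurium=sigma,
            saline=2.0,
        )
        r_mm = 1.0
        v = extracellular_potential((0, 0, 0), 1.0, (r_mm, 0, 0), cond)
        expected = 1e-6 / (4 * math.pi * sigma * 1e-3) * 1e3  # mV
        assert v == pytest.approx(expected, rel=1e-9)

    def test_linear_in_current(self):
        p = (0.3, -0.2, 0.9)
        v1 = extracellular_potential((0, 0, 0), 1.0, p, COND)
        v2 = extracellular_potential((0, 0, 0), 2.0, p, COND)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            extracellular_potential((1, 1, 1), 1.0, (1, 1, 1), COND)

    def test_axis_symmetry_matches_conductivity_tensor(self):
        # x and y are the transverse axes: swapping them leaves V unchanged
        va = extracellular_potential((0, 0, 0), 1.0, (0.4, 0.7, 0.2), COND)
        vb = extracellular_potential((0, 0, 0), 1.0, (0.7, 0.4, 0.2), COND)
        assert va == pytest.approx(vb, rel=1e-12)
        # equipotentials stretch along the high-conductivity axis: V at a
        # given distance along z (scaled by the two transverse sigmas) is
        # larger than at the same distance along x
        vz = extracellular_potential((0, 0, 0), 1.0, (0, 0, 1.0), COND)
        vx = extracellular_potential((0, 0, 0), 1.0, (1.0, 0, 0), COND)
        assert vz > vx
        assert vz / vx == pytest.approx(
            math.sqrt(COND.endoneurium[2] / COND.endoneurium[0]), rel=1e-9
        )

    def test_inverse_distance_decay(self):
        v1 = extracellular_potential((0, 0, 0), 1.0, (1.0, 0, 0), COND)
        v2 = extracellular_potential((0, 0, 0), 1.0, (2.0, 0, 0), COND)
        assert v1 / v2 == pytest.approx(2.0, rel=1e-12)

    def test_against_finite_difference_solve(self):
        # independent numerical check on a small grid: solve the anisotropic
        # Laplace equation with a 7-point stencil on a box with the source
        # region carved out (Dirichlet data on both boundaries from the
        # closed form); interior FD values must agree <= 2%
        from scipy.sparse import lil_matrix
        from scipy.sparse.linalg import spsolve

        sx, sy, sz = COND.endoneurium
        n = 33
        L = 4.0e-3  # box edge (m)
        h = L / (n - 1)
        coords = np.linspace(-L / 2, L / 2, n)
        c = n // 2
        I = 1e-6  # A

        def analytic(ix, iy, iz):
            dx, dy, dz = coords[ix], coords[iy], coords[iz]
            denom = math.sqrt(sy * sz * dx**2 + sx * sz * dy**2 + sx * sy * dz**2)
            return I / (4 * math.pi * denom)

        def is_fixed(i, j, k):
            if i in (0, n - 1) or j in (0, n - 1) or k in (0, n - 1):
                return True
            return abs(i - c) <= 6 and abs(j - c) <= 6 and abs(k - c) <= 6

        idx = lambda i, j, k: (i * n + j) * n + k
        A = lil_matrix((n**3, n**3))
        b = np.zeros(n**3)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    r = idx(i, j, k)
                    if is_fixed(i, j, k):
                        A[r, r] = 1.0
                        # the exact source node is never referenced by an
                        # interior equation; leave it at 0
                        b[r] = 0.0 if (i, j, k) == (c, c, c) else analytic(i, j, k)
                        continue
                    A[r, r] = -2.0 * (sx + sy + sz) / h**2
                    A[r, idx(i + 1, j, k)] = sx / h**2
                    A[r, idx(i - 1, j, k)] = sx / h**2
                    A[r, idx(i, j + 1, k)] = sy / h**2
                    A[r, idx(i, j - 1, k)] = sy / h**2
                    A[r, idx(i, j, k + 1)] = sz / h**2
                    A[r, idx(i, j, k - 1)] = sz / h**2
        v = spsolve(A.tocsr(), b)
        errs = [
            abs(v[idx(i, j, k)] - analytic(i, j, k)) / analytic(i, j, k)
            for i in range(1, n - 1)
            for j in range(1, n - 1)
            for k in range(1, n - 1)
            if not is_fixed(i, j, k)
        ]
        assert np.max(errs) <= 0.02

    def test_source_normalization_by_flux_integral(self):
        # total current through a closed box around the source must equal
        # the injected current (discrete Gauss law on the closed form)
        sx, sy, sz = COND.endoneurium
        sig = (sx, sy, sz)
        I_uA = 1.0
        a = 1.0  # half edge, mm
        m = 60  # surface sampling per face edge
        dh = 1e-4  # central-difference step, mm

        def V(p):  # mV at mm coordinates
            return extracellular_potential((0, 0, 0), I_uA, p, COND)

        total = 0.0
        for axis in range(3):
            for sign in (-1.0, 1.0):
                u = np.linspace(-a, a, m + 1)[:-1] + a / m
                U, W = np.meshgrid(u, u)
                flux = 0.0
                for uu, ww in zip(U.ravel(), W.ravel()):
                    p = [uu, ww]
                    p.insert(axis, sign * a)
                    p_hi = list(p)
                    p_lo = list(p)
                    p_hi[axis] += dh
                    p_lo[axis] -= dh
                    # J_n = -sigma dV/dn; V in mV, mm -> scale to SI below
                    dVdn = (V(p_hi) - V(p_lo)) / (2 * dh) * sign
                    flux += -sig[axis] * dVdn
                total += flux * (2.0 * a / m) ** 2  # mV/mm * S/m * mm^2
        # mV/mm * S/m * mm^2 = 1e-3 V * 1e3/m * S/m * 1e-6 m^2 = 1e-6 A = uA
        assert total == pytest.approx(I_uA, rel=0.02)


class TestPerineuriumCrossings:
    NERVE = nr.default_nerve()

    def test_interior_segment_no_crossings(self):
        assert perineurium_crossings((0.1, 0.0), (0.0, 0.2), self.NERVE) == 0

    def test_outside_to_inside_one_crossing(self):
        assert perineurium_crossings((-1.0, 0.0), (0.0, 0.0), self.NERVE) == 1

    def test_shielded_path_three_crossings(self):
        # through the medium fascicle (in + out) then into the target
        assert perineurium_crossings((1.65, 0.0), (0.0, 0.0), self.NERVE) == 3


class TestAxonResponse:
    PARAMS = AxonParams()

    def _phi(self, distance_mm=0.3, D=10.0):
        fasc = Fascicle((0.0, 0.0), 1.2, "large")
        nerve = NerveModel([fasc])
        return _node_phi(
            (distance_mm, 0.0), D, 0.0, (0.0, 0.0), nerve, COND, self.PARAMS, 0.3
        )

    def test_zero_amplitude_not_recruited(self):
        phi = self._phi()
        assert not axon_response(phi, 10.0, StimPulse(amplitude=1e-9, width=100.0))

    def test_threshold_decreases_with_diameter(self):
        fasc = Fascicle((0.0, 0.0), 1.2, "large")
        nerve = NerveModel([fasc])
        ths = []
        for D in (6.0, 9.0, 12.0):
            phi = _node_phi((0.45, 0.0), D, 0.0, (0.0, 0.0), nerve, COND, self.PARAMS, 0.3)
            ths.append(fiber_threshold(phi, D))
        assert ths[0] > ths[1] > ths[2]

    def test_threshold_increases_with_distance(self):
        ths = [fiber_threshold(self._phi(d), 10.0) for d in (0.15, 0.3, 0.5)]
        assert ths[0] < ths[1] < ths[2]


class TestPopulations:
    FASC = Fascicle((0.0, 0.0), 1.2, "large")

    def test_exactly_100_fibers_inside_fascicle(self):
        pop = sample_population(self.FASC, 1, seed=0)
        assert pop.n_fibers == 100
        r = np.hypot(*(pop.positions - self.FASC.center).T)
        assert np.all(r <= self.FASC.radius)

    def test_extent_nesting(self):
        wide = sample_population(self.FASC, 1, seed=0)
        tight = sample_population(self.FASC, 9, seed=0)
        spread = lambda p: np.hypot(
            *(p.positions - p.positions.mean(axis=0)).T
        ).max()
        assert spread(wide) > spread(tight)
        # the tight cluster still lies inside the full-fascicle disc
        r = np.hypot(*(tight.positions - self.FASC.center).T)
        assert np.all(r <= 0.95 * self.FASC.radius + 1e-9)

    def test_same_seed_identical(self):
        a = sample_population(self.FASC, 3, seed=5)
        b = sample_population(self.FASC, 3, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.diameters, b.diameters)

    def test_invalid_population_id_rejected(self):
        with pytest.raises(ValueError):
            sample_population(self.FASC, 10, seed=0)
        small = Fascicle((0.0, 0.0), 0.35, "small")
        with pytest.raises(ValueError):
            sample_population(small, 2, seed=0)

    def test_diameters_truncated_gaussian(self):
        pop = sample_population(self.FASC, 1, seed=1, n_fibers=100)
        assert np.all(pop.diameters > 3.0)
        assert 7.0 < pop.diameters.mean() < 11.0


class TestSimulationPlan:
    def test_case_counts_45_needle_90_time(self):
        plan = enumerate_simulation_plan()
        assert sum(c.device == "needle" for c in plan) == 45
        assert sum(c.device == "TIME" for c in plan) == 90

    def test_case_keys_unique(self):
        plan = enumerate_simulation_plan()
        keys = [c.key for c in plan]
        assert len(set(keys)) == len(keys) == 135


class TestRecruitmentCurves:
    def test_zero_charge_zero_fraction(self):
        curve = RecruitmentCurve(
            charges=np.array([0.0, 1.0, 2.0]),
            fraction_recruited=np.array([0.0, 0.5, 1.0]),
            thresholds_nC=np.array([0.8, 1.5]),
        )
        assert curve.fraction_recruited[0] == 0.0
        assert curve.charge_at(0.5) == pytest.approx(1.0)
        assert np.isnan(
            RecruitmentCurve(
                charges=np.array([1.0]),
                fraction_recruited=np.array([0.05]),
                thresholds_nC=np.array([np.inf]),
            ).charge_at(0.10)
        )

    def test_small_plan_monotone_and_ordered(self):
        # single large-fascicle population, needle at all three placements
        nerve = nr.default_nerve()
        cases = [
            c
            for c in enumerate_simulation_plan(nerve)
            if c.device == "needle" and c.fascicle_class == "large" and c.population_id == 1
        ]
        grid = np.linspace(0.25, 60.0, 80)
        results = nr.run_plan(seed=1, nerve=nerve, n_fibers=8, charge_grid=grid, cases=cases)
        charges = {}
        for key, curve in results.items():
            assert np.all(np.diff(curve.fraction_recruited) >= 0)
            assert np.all((curve.fraction_recruited >= 0) & (curve.fraction_recruited <= 1))
            q = curve.charge_at(0.10)
            charges[key[1]] = q if np.isfinite(q) else np.inf
        assert charges["within"] < charges["close"] <= charges["shielded"]


class TestDeviceComparison:
    def _curve(self, thresholds, key):
        grid = np.linspace(0.5, 50, 100)
        th = np.asarray(thresholds, dtype=float)
        return RecruitmentCurve(
            charges=grid,
            fraction_recruited=np.array([np.mean(th <= c) for c in grid]),
            thresholds_nC=th,
            case_key=key,
        )

    def test_identical_threshold_sets_no_difference(self):
        th = [1.0, 2.0, 3.0, 4.0, 5.0]
        results = {}
        for i in range(4):
            results[("needle", "within", "large", i, "tip")] = self._curve(th, None)
            results[("TIME", "within", "large", i, "L")] = self._curve(th, None)
        comp = compare_devices(results)
        assert comp.p_value == pytest.approx(1.0)
        assert not comp.significant

    def test_tenfold_shift_detected(self):
        rng = np.random.default_rng(0)
        results = {}
        for i in range(8):
            th = rng.uniform(1, 5, size=10)
            results[("needle", "within", "large", i, "tip")] = self._curve(th, None)
            results[("TIME", "within", "large", i, "L")] = self._curve(th * 10, None)
        comp = compare_devices(results)
        assert comp.significant

    def test_empty_group_rejected(self):
        results = {("needle", "within", "large", 1, "tip"): self._curve([1.0], None)}
        with pytest.raises(ValueError):
            compare_devices(results)


class TestValidation:
    def test_conductivity_invariants(self):
        with pytest.raises(ValueError):
            TissueConductivities(endoneurium=(0.5, 0.5, 0.4))
        with pytest.raises(ValueError):
            TissueConductivities(perineurium=0.0)

    def test_fascicles_must_be_disjoint(self):
        with pytest.raises(ValueError):
            NerveModel(
                [
                    Fascicle((0.0, 0.0), 1.0, "large"),
                    Fascicle((0.5, 0.0), 1.0, "large"),
                ]
            )

    def test_perineurium_thickness_rule(self):
        f = Fascicle((0, 0), 1.0, "large")
        assert f.perineurium_thickness == pytest.approx(0.03)

    def test_pulse_charge(self):
        assert StimPulse(amplitude=160.0, width=100.0).charge_nC == pytest.approx(16.0)
        with pytest.raises(ValueError):
            StimPulse(amplitude=0.0, width=100.0)
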