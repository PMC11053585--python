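"""SL(2,R) formalism: stationary waves, Schwarzian, Moebius action,
Lie algebra, Cartan coframe, Riccati gauge."""

import numpy as np
import pytest
import sympy as sp

from mfrelease import (
    ClosedFormParams,
    CoframeValues,
    MobiusTransform,
    ScaleParams,
    StateTriple,
    WaveMode,
    closed_form_solution,
    coeffs_from_gauge,
    coframe_eval,
    coframe_reconstruct,
    commutator,
    generators,
    integrate_riccati,
    k0_from_energy,
    mobius_apply,
    personal_parameter,
    riccati_gauge,
    schwarzian,
    stationary_wave,
)
from mfrelease.algebra import K, Z, ZBAR, VectorField
from mfrelease.errors import DegenerateStateError, DomainError, PoleError


class TestWavenumber:
    def test_zero_energy(self):
        assert k0_from_energy(0.0, 1.0, ScaleParams()) == 0.0

    @pytest.mark.parametrize(
        "E,m0,scale,expected",
        [
            (2.0, 1.0, ScaleParams(lam=1.0, dt_res=0.3, f_alpha=2.0), 2.0),
            (0.5, 1.0, ScaleParams(lam=1.0, dt_res=1.0, f_alpha=1.5), 1.0),
        ],
    )
    def test_values(self, E, m0, scale, expected):
        assert k0_from_energy(E, m0, scale) == pytest.approx(expected)

    def test_negative_energy_rejected(self):
        with pytest.raises(DomainError):
            k0_from_energy(-1.0, 1.0, ScaleParams())


class TestStationaryWave:
    def test_cosine_for_real_half_amplitude(self):
        mode = WaveMode(E=0.5, m0=1.0, scale=ScaleParams(), z_amp=0.5)
        x = np.linspace(0, 5, 50)
        psi = stationary_wave(mode, x)
        assert np.allclose(psi, np.cos(mode.k0 * x))
        assert np.max(np.abs(np.imag(psi))) < 1e-15

    def test_sine_for_imaginary_amplitude(self):
        mode = WaveMode(E=0.5, m0=1.0, scale=ScaleParams(), z_amp=1 / 2j)
        x = np.linspace(0, 5, 50)
        assert np.allclose(stationary_wave(mode, x), np.sin(mode.k0 * x))

    def test_helmholtz_residual_second_order(self):
        # Psi'' + k0^2 Psi -> 0 at O(h^2) under refinement
        mode = WaveMode(E=2.0, m0=1.0, scale=ScaleParams(), z_amp=0.3 + 0.4j, theta=0.2)
        errs = []
        for h in (1e-2, 5e-3):
            x = np.arange(-1.0, 1.0 + h / 2, h)
            psi = np.real(stationary_wave(mode, x))
            lap = (psi[2:] - 2 * psi[1:-1] + psi[:-2]) / h**2
            errs.append(np.max(np.abs(lap + mode.k0**2 * psi[1:-1])))
        assert errs[1] < errs[0] / 3.0  # ~factor 4 for O(h^2)


class TestSchwarzian:
    def test_tan_gives_two(self):
        for x in np.linspace(0.1, 1.2, 50):
            assert schwarzian(np.tan, x) == pytest.approx(2.0, abs=1e-6)

    def test_tan_2x_gives_eight(self):
        assert schwarzian(lambda x: np.tan(2 * x), 0.3) == pytest.approx(8.0, abs=1e-5)

    def test_moebius_invariance(self):
        M = MobiusTransform(2.0, 1.0, 1.0, 1.0)

        def mobius_of_tan(t):
            u = np.tan(t)
            return (M.a * u + M.b) / (M.c * u + M.d)

        for x in (0.3, 0.7, 1.1):
            assert schwarzian(mobius_of_tan, x) == pytest.approx(2.0, abs=1e-6)

    def test_critical_point_rejected(self):
        with pytest.raises(DomainError):
            schwarzian(lambda x: x**2, 0.0)


class TestPersonalParameter:
    def test_constant_when_v_zero(self):
        assert personal_parameter(1.3, 0.0, 0.0, 2.0, 0.5) == 1.3

    def test_tan_unit(self):
        assert personal_parameter(0.0, 1.0, 0.0, 1.0, np.pi / 4) == pytest.approx(1.0)

    def test_amplitude_form_identity(self, rng):
        """u + v*tan(k0 x + theta) == (z + zbar*eps)/(1 + eps) with
        z = u + i v, eps = exp(2i(k0 x + theta))."""
        for _ in range(100):
            u, v = rng.normal(), rng.normal()
            theta, k0, x = rng.normal(), rng.uniform(0.5, 3), rng.normal()
            if abs(np.cos(k0 * x + theta)) < 1e-3:
                continue
            z = complex(u, v)
            eps = np.exp(2j * (k0 * x + theta))
            rhs = (z + np.conj(z) * eps) / (1 + eps)
            lhs = personal_parameter(u, v, theta, k0, x)
            assert lhs == pytest.approx(np.real(rhs), abs=1e-9)
            assert abs(np.imag(rhs)) < 1e-9

    def test_pole(self):
        with pytest.raises(PoleError):
            personal_parameter(0.0, 1.0, 0.0, 1.0, np.pi / 2)


class TestMobius:
    def test_identity_fixes_state(self):
        s = StateTriple.physical(0.3 + 1.2j, 2.0 - 0.5j)
        out = mobius_apply(MobiusTransform.identity(), s)
        assert out == s

    def test_elliptic_fixed_point(self):
        M = MobiusTransform(0.0, 1.0, -1.0, 0.0)
        s = StateTriple.physical(1j, 1.0)
        out = mobius_apply(M, s)
        assert out.z == pytest.approx(1j)

    def test_k_modulus_conserved_on_physical_states(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=3)
            d = (1 + b * c) / a if a != 0 else 1.0
            try:
                M = MobiusTransform(a, b, c, d)
            except DomainError:
                continue
            s = StateTriple.physical(
                complex(rng.normal(), abs(rng.normal()) + 0.1),
                complex(rng.normal(), rng.normal()),
            )
            out = mobius_apply(M, s)
            assert abs(abs(out.k) - abs(s.k)) < 1e-12 * max(1.0, abs(s.k))
            assert out.zbar == pytest.approx(np.conj(out.z))

    def test_composition_is_matrix_product(self, rng):
        M1 = MobiusTransform(1.0, 2.0, 0.5, 3.0)
        M2 = MobiusTransform(2.0, -1.0, 1.0, 0.5)
        z = 0.7 + 1.3j
        assert M1.compose(M2).apply_scalar(z) == pytest.approx(
            M1.apply_scalar(M2.apply_scalar(z))
        )

    def test_inverse_composes_to_identity(self):
        M = MobiusTransform(3.0, 1.0, 2.0, 1.0)
        MI = M.compose(M.inverse())
        z = 0.2 + 0.9j
        assert MI.apply_scalar(z) == pytest.approx(z, abs=1e-12)

    def test_normalized_to_unit_det(self):
        M = MobiusTransform(2.0, 0.0, 0.0, 2.0)
        assert M.a * M.d - M.b * M.c == pytest.approx(1.0)

    def test_singular_rejected(self):
        with pytest.raises(DomainError):
            MobiusTransform(1.0, 2.0, 2.0, 4.0)


class TestLieAlgebra:
    def test_commutator_table_exact(self):
        L1, L2, L3 = generators()
        assert commutator(L1, L2) == L1
        assert commutator(L2, L3) == L3
        assert commutator(L3, L1) == -2 * L2

    def test_antisymmetry(self):
        _, L2, L3 = generators()
        assert commutator(L3, L3).is_zero()
        assert (commutator(L2, L3) + commutator(L3, L2)).is_zero()

    def test_jacobi_identity(self):
        L1, L2, L3 = generators()
        s = (
            commutator(L1, commutator(L2, L3))
            + commutator(L2, commutator(L3, L1))
            + commutator(L3, commutator(L1, L2))
        )
        assert s.is_zero()

    def test_generator_action_on_functions(self):
        L1, L2, L3 = generators()
        assert sp.expand(L1(Z) - 1) == 0
        assert sp.expand(L2(Z * ZBAR) - 2 * Z * ZBAR) == 0
        assert sp.expand(L3(K) - (Z - ZBAR) * K) == 0

    def test_custom_field_arithmetic(self):
        X = VectorField(Z, sp.Integer(0), sp.Integer(0))
        Y = VectorField(sp.Integer(1), sp.Integer(0), sp.Integer(0))
        assert commutator(X, Y) == VectorField(sp.Integer(-1), sp.Integer(0), sp.Integer(0))


class TestCoframe:
    def test_worked_point(self):
        s = StateTriple(z=1j, zbar=-1j, k=1.0)
        w = coframe_eval(s, (0.1, 0.1, 0.0))
        assert (w.w1, w.w2, w.w3) == pytest.approx((0.0, 0.0, 0.1))
        assert coframe_reconstruct(s, w) == pytest.approx((0.1, 0.1, 0.0))

    def test_zero_displacement(self):
        s = StateTriple.physical(0.5 + 2j, 1.0 + 1j)
        w = coframe_eval(s, (0.0, 0.0, 0.0))
        assert (w.w1, w.w2, w.w3) == (0.0, 0.0, 0.0)
        assert coframe_reconstruct(s, CoframeValues(0.0, 0.0, 0.0)) == (0.0, 0.0, 0.0)

    def test_round_trip_identity(self, rng):
        for _ in range(100):
            s = StateTriple.physical(
                complex(rng.normal(), abs(rng.normal()) + 0.05),
                complex(rng.normal(), rng.normal()),
            )
            ds = tuple(complex(rng.normal(), rng.normal()) for _ in range(3))
            back = coframe_reconstruct(s, coframe_eval(s, ds))
            scale = max(1.0, max(abs(d) for d in ds))
            assert max(abs(a - b) for a, b in zip(ds, back)) <= 1e-12 * scale

    def test_reverse_round_trip_identity(self, rng):
        for _ in range(50):
            s = StateTriple.physical(
                complex(rng.normal(), abs(rng.normal()) + 0.05),
                complex(rng.normal(), rng.normal()),
            )
            w = CoframeValues(*(complex(rng.normal(), rng.normal()) for _ in range(3)))
            w2 = coframe_eval(s, coframe_reconstruct(s, w))
            err = max(abs(w.w1 - w2.w1), abs(w.w2 - w2.w2), abs(w.w3 - w2.w3))
            assert err <= 1e-11

    def test_real_state_rejected(self):
        with pytest.raises(DegenerateStateError):
            coframe_eval(StateTriple(1.0, 1.0, 1.0), (0.1, 0.1, 0.0))


class TestRiccatiGauge:
    def test_unit_geodesic(self):
        g = riccati_gauge(CoframeValues(0.01, 0.0, 0.01), 0.01)
        assert (g.a1, g.a2, g.a3) == (1.0, 0.0, 1.0)
        assert coeffs_from_gauge(g).omega == 1.0

    def test_homogeneity(self):
        w = CoframeValues(0.02, -0.01, 0.03)
        g1 = riccati_gauge(w, 0.01)
        g2 = riccati_gauge(CoframeValues(0.2, -0.1, 0.3), 0.1)
        assert (g1.a1, g1.a2, g1.a3) == pytest.approx((g2.a1, g2.a2, g2.a3))

    def test_zero_dtau_rejected(self):
        with pytest.raises(DomainError):
            riccati_gauge(CoframeValues(0.01, 0.0, 0.01), 0.0)

    def test_gauge_to_closed_form_end_to_end(self):
        """Symmetry-to-dynamics loop: a geodesic gauge integrates to the
        same trajectory as the closed form of the mapped oscillator."""
        g = riccati_gauge(CoframeValues(0.005, 0.0, 0.02), 0.005)  # a=(1,0,4)
        c = coeffs_from_gauge(g)
        p = ClosedFormParams(r=0.5)
        taus = np.linspace(0.0, 5.0, 201)
        zc = closed_form_solution(c, p, taus)
        zn = integrate_riccati(zc[0], c, taus)
        assert np.max(np.abs(zc - zn)) < 1e-6
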