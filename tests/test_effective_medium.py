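"""Bruggeman mixing, the combined-equation solvers, and their diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thzem.effective_medium import (
    EffectiveMediumError,
    SolutionTriplet,
    bruggeman2_effective,
    bruggeman2_residual,
    bruggeman3_effective,
    bruggeman3_residual,
    extract_spectrum,
    full_polynomial_coefficients,
    full_residual,
    protein_from_shell,
    sensitivity_scan,
    shell_from_concentrated,
    solve_protein_full,
    solve_protein_reduced,
    term_magnitudes,
)
from thzem.fractions import PhaseFractions
from thzem.spectra_io import DielectricSpectrum, FrequencyGrid

EPS0 = 4.0 + 1.0j  # generic homogeneous permittivity


def _bisect_real_residual(eps_a, eps_b, f_a, lo, hi, tol=1e-12):
    """Independent oracle: bisect the real two-phase residual."""

    def g(x):
        return bruggeman2_residual(eps_a, eps_b, x, f_a).real

    assert g(lo) * g(hi) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestBruggemanTwoPhase:
    def test_homogeneous_residual_zero(self):
        assert bruggeman2_residual(EPS0, EPS0, EPS0, 0.3) == 0

    def test_pure_phase_b(self):
        assert bruggeman2_residual(3.0, 5.0, 5.0, 0.0) == 0

    def test_antisymmetry(self):
        r1 = bruggeman2_residual(3 + 0.2j, 5 + 1j, 4 + 0.5j, 0.3)
        r2 = bruggeman2_residual(5 + 1j, 3 + 0.2j, 4 + 0.5j, 0.7)
        assert r1 == pytest.approx(r2, rel=1e-14)

    def test_forward_matches_bisection_oracle(self):
        root = _bisect_real_residual(3.0, 5.0, 0.3, 3.0, 5.0)
        got = bruggeman2_effective(3.0, 5.0, 0.3)
        assert got.real == pytest.approx(root, abs=1e-10)
        assert got.real == pytest.approx(4.3315, abs=1e-4)
        assert got.imag == pytest.approx(0.0, abs=1e-12)

    def test_forward_residual_small(self):
        eps_e = bruggeman2_effective(3 + 0.3j, 5 + 1.2j, 0.3)
        res = bruggeman2_residual(3 + 0.3j, 5 + 1.2j, eps_e, 0.3)
        assert abs(res) < 1e-10

    @pytest.mark.parametrize("f", [1e-12, 0.0])
    def test_vanishing_inclusion_limit(self, f):
        got = bruggeman2_effective(3 + 0.5j, 5 + 1j, f)
        assert got == pytest.approx(5 + 1j, rel=1e-9)

    def test_homogeneous_forward(self):
        assert bruggeman2_effective(EPS0, EPS0, 0.42) == pytest.approx(EPS0, rel=1e-14)

    @given(
        ea=st.floats(1.0, 20.0),
        eb=st.floats(1.0, 20.0),
        f=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_wiener_bounds_real_lossless(self, ea, eb, f):
        e = bruggeman2_effective(ea, eb, f)
        assert abs(e.imag) < 1e-10
        lo, hi = min(ea, eb), max(ea, eb)
        assert lo - 1e-9 <= e.real <= hi + 1e-9

    def test_monotone_in_fraction_real(self):
        fs = np.linspace(0.05, 0.95, 10)
        vals = [bruggeman2_effective(2.0, 9.0, f).real for f in fs]
        assert np.all(np.diff(vals) < 0)  # more of the low-eps phase lowers eps_e


class TestShellRelation:
    def test_homogeneous_identity(self):
        assert shell_from_concentrated(EPS0, EPS0, 0.237) == pytest.approx(EPS0, rel=1e-14)

    def test_residual_zero_after_substitution(self):
        eps_p, eps_cs, f_p = 2 + 0.5j, 4 + 1j, 0.237
        eps_sh = shell_from_concentrated(eps_p, eps_cs, f_p)
        res = bruggeman2_residual(eps_p, eps_sh, eps_cs, f_p)
        assert abs(res) < 1e-12

    def test_direct_formula_value(self):
        eps_p, eps_cs, f_p = 2 + 0.5j, 4 + 1j, 0.237
        expected = ((1 - 3 * f_p) * eps_p * eps_cs + 2 * eps_cs**2) / (
            eps_p + (2 - 3 * f_p) * eps_cs
        )
        assert shell_from_concentrated(eps_p, eps_cs, f_p) == pytest.approx(expected, rel=1e-14)

    def test_roundtrip_with_forward_mixture(self):
        eps_p, eps_sh, f_p = 2.6 + 0.4j, 3.5 + 2.2j, 0.237
        eps_cs = bruggeman2_effective(eps_p, eps_sh, f_p)
        back = shell_from_concentrated(eps_p, eps_cs, f_p)
        assert back == pytest.approx(eps_sh, rel=1e-10)

    def test_inversion_roundtrip(self):
        eps_p, eps_cs, f_p = 2 + 0.5j, 4 + 1j, 0.237
        eps_sh = shell_from_concentrated(eps_p, eps_cs, f_p)
        assert protein_from_shell(eps_sh, eps_cs, f_p) == pytest.approx(eps_p, rel=1e-12)


class TestBruggemanThreePhase:
    def test_homogeneous_residual_zero(self):
        assert bruggeman3_residual(EPS0, EPS0, EPS0, EPS0, 0.05, 0.1) == 0

    def test_reduces_to_two_phase_at_zero_protein(self):
        eps_sh, eps_w, eps_s = 3.5 + 2j, 4.3 + 5j, 4.2 + 4.8j
        r3 = bruggeman3_residual(2.6 + 0.4j, eps_sh, eps_w, eps_s, 0.0, 0.114)
        r2 = bruggeman2_residual(eps_sh, eps_w, eps_s, 0.114)
        assert r3 == pytest.approx(r2, rel=1e-14)

    def test_forward_residual_small(self, fractions):
        eps_s = bruggeman3_effective(
            2.6 + 0.4j, 3.5 + 2.2j, 4.3 + 5.5j, fractions.f, fractions.f_sh
        )
        res = bruggeman3_residual(
            2.6 + 0.4j, 3.5 + 2.2j, 4.3 + 5.5j, eps_s, fractions.f, fractions.f_sh
        )
        assert np.all(np.abs(res) < 1e-10)

    def test_homogeneous_forward(self, fractions):
        got = bruggeman3_effective(EPS0, EPS0, EPS0, fractions.f, fractions.f_sh)
        assert got == pytest.approx(np.atleast_1d(EPS0), rel=1e-12)

    def test_vanishing_inclusions_give_water(self):
        got = bruggeman3_effective(2.6 + 0.4j, 3.5 + 2.2j, 4.3 + 5.5j, 1e-13, 1e-13)
        assert got == pytest.approx(np.atleast_1d(4.3 + 5.5j), rel=1e-9)


class TestCombinedEquation:
    def test_homogeneous_residual_zero(self, fractions):
        total, _ = full_residual(EPS0, EPS0, EPS0, EPS0, fractions)
        assert abs(total) < 1e-15

    def test_first_term_is_protein_term(self, fractions):
        eps_p, eps_w, eps_s, eps_cs = 2.6 + 0.4j, 4.3 + 5.5j, 4.2 + 4.9j, 3.9 + 4.2j
        _, (t1, _, _) = full_residual(eps_p, eps_w, eps_s, eps_cs, fractions)
        expected = fractions.f * (eps_p - eps_s) / (eps_p + 2 * eps_s)
        assert t1 == pytest.approx(expected, rel=1e-14)

    def test_combined_equals_three_phase_with_expressed_shell(self, fractions):
        eps_p, eps_w, eps_s, eps_cs = 2.6 + 0.4j, 4.3 + 5.5j, 4.2 + 4.9j, 3.9 + 4.2j
        eps_sh = shell_from_concentrated(eps_p, eps_cs, fractions.f_p)
        total, _ = full_residual(eps_p, eps_w, eps_s, eps_cs, fractions)
        direct = bruggeman3_residual(
            eps_p, eps_sh, eps_w, eps_s, fractions.f, fractions.f_sh
        )
        assert total == pytest.approx(direct, rel=1e-14)

    def test_polynomial_matches_rational_form(self, fractions):
        # the cleared-denominator quadratic and the rational residual agree
        # up to the cleared factor, at an arbitrary trial point
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.2 + 4.9j, 3.9 + 4.2j
        x = 2.8 + 0.7j
        c2, c1, c0 = full_polynomial_coefficients(eps_w, eps_s, eps_cs, fractions)[:, 0]
        poly_val = c2 * x**2 + c1 * x + c0
        total, _ = full_residual(x, eps_w, eps_s, eps_cs, fractions)
        n1 = (1 - 3 * fractions.f_p) * eps_cs
        n0 = 2 * eps_cs**2
        d0 = (2 - 3 * fractions.f_p) * eps_cs
        cleared = (x + 2 * eps_s) * (n1 * x + n0 + 2 * eps_s * (x + d0))
        assert poly_val == pytest.approx(total * cleared, rel=1e-12)

    def test_quadratic_degree(self, fractions):
        coeffs = full_polynomial_coefficients(4.3 + 5.5j, 4.2 + 4.9j, 3.9 + 4.2j, fractions)
        assert coeffs.shape[0] == 3
        assert abs(coeffs[0, 0]) > 1e-6 * abs(coeffs).max()  # genuinely degree 2


class TestReducedSolver:
    def test_homogeneous_limit(self, fractions):
        got = solve_protein_reduced(EPS0, EPS0, EPS0, fractions)
        assert got == pytest.approx(EPS0, rel=1e-12)

    def test_neglected_terms_cancel_at_solution(self, fractions):
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.25 + 5.3j, 3.9 + 4.2j
        eps_p = solve_protein_reduced(eps_w, eps_s, eps_cs, fractions)
        _, (_, t2, t3) = full_residual(eps_p, eps_w, eps_s, eps_cs, fractions)
        assert abs(t2 + t3) < 1e-14

    def test_error_vanishes_with_protein_fraction(self, fractions):
        # forward-generate with shrinking f; reduced recovery error -> 0
        eps_p, eps_sh, eps_w = 2.6 + 0.4j, 3.5 + 2.2j, 4.3 + 5.5j
        eps_cs = bruggeman2_effective(eps_p, eps_sh, fractions.f_p)
        errors = []
        for scale in (1.0, 0.5, 0.25, 0.125):
            fr = fractions.scale_protein(scale)
            eps_s = bruggeman3_effective(eps_p, eps_sh, eps_w, fr.f, fr.f_sh)
            got = solve_protein_reduced(eps_w, eps_s, eps_cs, fr)
            errors.append(abs(got - eps_p) / abs(eps_p))
        assert np.all(np.diff(errors) < 0)
        assert errors[-1] < errors[0] / 4


class TestFullSolver:
    def test_homogeneous_limit(self, fractions):
        got, meta = solve_protein_full(EPS0, EPS0, EPS0, fractions)
        assert got[0] == pytest.approx(EPS0, rel=1e-10)
        assert meta["residual"][0] < 1e-10

    def test_exact_roundtrip(self, fractions):
        # strong protein contrast: both quadratic roots are physical, so the
        # truth-adjacent branch must be selected via the hint
        eps_p, eps_sh, eps_w = 2.6 + 0.4j, 3.5 + 2.2j, 4.3 + 5.5j
        eps_cs = bruggeman2_effective(eps_p, eps_sh, fractions.f_p)
        eps_s = bruggeman3_effective(eps_p, eps_sh, eps_w, fractions.f, fractions.f_sh)
        got, meta = solve_protein_full(eps_w, eps_s, eps_cs, fractions, hint=2.5 + 0.3j)
        assert got[0] == pytest.approx(eps_p, rel=1e-8)
        assert meta["residual"][0] < 1e-10
        assert meta["n_physical"][0] >= 1

    def test_both_branches_solve_the_equation(self, fractions):
        # the combined equation is quadratic: its two roots are both exact
        # solutions and selection between them is by hint alone
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.25 + 5.3j, 3.9 + 4.2j
        c2, c1, c0 = full_polynomial_coefficients(eps_w, eps_s, eps_cs, fractions)[:, 0]
        roots = np.roots([c2, c1, c0])
        assert roots.size == 2
        for r in roots:
            total, terms = full_residual(r, eps_w, eps_s, eps_cs, fractions)
            assert abs(total) / max(abs(t) for t in terms) < 1e-10

    def test_respects_hint(self, fractions):
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.25 + 5.3j, 3.9 + 4.2j
        got, _ = solve_protein_full(eps_w, eps_s, eps_cs, fractions, hint=2.6 + 0.4j)
        # solves the equation regardless of which root was picked
        total, terms = full_residual(got[0], eps_w, eps_s, eps_cs, fractions)
        assert abs(total) / max(abs(t) for t in terms) < 1e-10


def _uniform_triplet(grid, value):
    m = len(grid)
    spec = DielectricSpectrum(
        grid=grid, eps_re=np.full(m, value.real), eps_im=np.full(m, value.imag)
    )
    return SolutionTriplet(eps_w=spec, eps_s=spec, eps_cs=spec)


class TestTermMagnitudes:
    def test_protein_term_scales_with_f(self, fractions):
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.25 + 5.3j, 3.9 + 4.2j
        eps_p = solve_protein_reduced(eps_w, eps_s, eps_cs, fractions)
        (a1, _, _), _ = term_magnitudes(eps_p, eps_w, eps_s, eps_cs, fractions)
        small = fractions.scale_protein(1e-6)
        (a1_small, _, _), _ = term_magnitudes(eps_p, eps_w, eps_s, eps_cs, small)
        assert a1_small == pytest.approx(a1 * 1e-6, rel=1e-6)

    def test_infinite_ratio_invalidates_everything(self, fractions):
        eps_w, eps_s, eps_cs = 4.3 + 5.5j, 4.25 + 5.3j, 3.9 + 4.2j
        eps_p = solve_protein_reduced(eps_w, eps_s, eps_cs, fractions)
        _, valid = term_magnitudes(eps_p, eps_w, eps_s, eps_cs, fractions, ratio=np.inf)
        assert not np.any(valid)


class TestExtractSpectrum:
    def test_identical_spectra_return_themselves(self, grid, fractions):
        triplet = _uniform_triplet(grid, EPS0)
        for solver in ("reduced", "full"):
            res = extract_spectrum(triplet, fractions, solver=solver)
            assert res.eps_p.eps == pytest.approx(np.full(len(grid), EPS0), rel=1e-9)
            assert res.solver_ok.all()

    def test_window_flagging(self, fractions):
        grid = FrequencyGrid(np.array([5.0, 30.0, 80.0]))
        triplet = _uniform_triplet(grid, EPS0)
        res = extract_spectrum(triplet, fractions, solver="reduced")
        assert list(res.in_window) == [False, True, False]
        assert not res.valid[0] and not res.valid[2]

    def test_singular_frequency_is_isolated(self, grid, fractions):
        # rig one frequency so the reduced solve hits its C = 1 singularity:
        # (1 - f - f_sh)(eps_w - eps_s) + f_sh (eps_w + 2 eps_s) = 0
        m = len(grid)
        f, f_sh = fractions.f, fractions.f_sh
        w = np.full(m, 5.0)
        s = np.full(m, 5.0)
        k = m // 2
        s[k] = 5.0 * (1 - f) / (1 - f - 3 * f_sh)
        triplet = SolutionTriplet(
            eps_w=DielectricSpectrum(grid=grid, eps_re=w, eps_im=np.zeros(m)),
            eps_s=DielectricSpectrum(grid=grid, eps_re=s, eps_im=np.zeros(m)),
            eps_cs=DielectricSpectrum(grid=grid, eps_re=w, eps_im=np.zeros(m)),
        )
        res = extract_spectrum(triplet, fractions, solver="reduced")
        assert not res.solver_ok[k]
        assert res.solver_ok[np.arange(m) != k].all()

    def test_unknown_solver_rejected(self, grid, fractions):
        with pytest.raises(EffectiveMediumError):
            extract_spectrum(_uniform_triplet(grid, EPS0), fractions, solver="magic")

    def test_mismatched_grids_rejected(self, grid, fractions):
        other = FrequencyGrid(grid.wavenumbers + 1.0)
        m = len(grid)
        a = DielectricSpectrum(grid=grid, eps_re=np.full(m, 4.0), eps_im=np.ones(m))
        b = DielectricSpectrum(grid=other, eps_re=np.full(m, 4.0), eps_im=np.ones(m))
        with pytest.raises(Exception, match="grid"):
            SolutionTriplet(eps_w=a, eps_s=b, eps_cs=a)


class TestSensitivityScan:
    def test_zero_delta_gives_zero_spread(self, noiseless_scene):
        rep = sensitivity_scan(
            noiseless_scene.triplet(),
            noiseless_scene.fractions,
            delta=0.0,
            n_draws=2,
            seed=1,
            solver="both",
        )
        for spread in rep.spreads.values():
            assert np.nanmax(spread.rel_sd) == 0.0
            assert np.nanmax(spread.maxmin_ratio) == pytest.approx(1.0)

    def test_reproducible_from_seed(self, noiseless_scene):
        kwargs = dict(delta=0.01, n_draws=5, seed=123, solver="reduced")
        r1 = sensitivity_scan(noiseless_scene.triplet(), noiseless_scene.fractions, **kwargs)
        r2 = sensitivity_scan(noiseless_scene.triplet(), noiseless_scene.fractions, **kwargs)
        assert np.array_equal(r1.spreads["reduced"].rel_sd, r2.spreads["reduced"].rel_sd)

    def test_input_validation(self, noiseless_scene):
        with pytest.raises(EffectiveMediumError):
            sensitivity_scan(
                noiseless_scene.triplet(), noiseless_scene.fractions,
                delta=-0.1, n_draws=5, seed=0,
            )
        with pytest.raises(EffectiveMediumError):
            sensitivity_scan(
                noiseless_scene.triplet(), noiseless_scene.fractions,
                delta=0.01, n_draws=1, seed=0,
            )
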