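"""Bruggeman mixing models and the protein-permittivity inversion.

The symmetric Bruggeman effective-medium approximation balances the
volume-fraction-weighted polarizabilities of a composite's phases around
the effective permittivity ``eps_e``:

    sum_i f_i (eps_i - eps_e) / (eps_i + 2 eps_e) = 0.

Three instances matter here.  The concentrated protein solution is a
two-phase mixture of protein (fraction ``f_p``) and hydration-shell water,
which fixes the shell permittivity ``eps_sh`` in closed form given the
measured ``eps_cs`` and a candidate protein permittivity.  The dilute
solution is a three-phase mixture of protein (``f``), shells (``f_sh``)
and bulk water.  Substituting the closed-form shell into the three-phase
balance leaves one equation per frequency in the single unknown protein
permittivity ``eps_p``:

    T1 + T2 + T3 = 0,

with T1 the protein term (weight ``f``), T2 the shell term (weight
``f_sh``) and T3 the bulk-water term.  Clearing denominators makes this a
quadratic in ``eps_p`` — the *full* solver.  Because ``f`` is small, T1 is
small, and the quadratic's coefficients are dominated by near-cancelling
contributions; the roots react violently to per-point errors of the size
seen in measured spectra (~0.01 on permittivity).  Dropping T1 linearises
the problem — the *reduced* solver: the shell permittivity follows
directly from ``eps_w`` and ``eps_s``, and inverting the two-phase
closed form yields a unique ``eps_p``.  The price is a bias of order
``|T1|/|T2|``, so every reduced solution carries a per-frequency validity
check that T2 and T3 exceed T1 by a configurable ratio (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fractions import PhaseFractions
from .spectra_io import DielectricSpectrum, FrequencyGrid, SpectrumError

__all__ = [
    "SolutionTriplet",
    "ExtractionResult",
    "SensitivityReport",
    "SolverSpread",
    "EffectiveMediumError",
    "bruggeman2_residual",
    "bruggeman2_effective",
    "shell_from_concentrated",
    "protein_from_shell",
    "bruggeman3_residual",
    "bruggeman3_effective",
    "full_residual",
    "full_polynomial_coefficients",
    "solve_protein_reduced",
    "solve_protein_full",
    "term_magnitudes",
    "extract_spectrum",
    "sensitivity_scan",
    "DEFAULT_VALIDITY_RATIO",
    "DEFAULT_WINDOW",
    "DEFAULT_TOL_NEG",
]

DEFAULT_VALIDITY_RATIO = 10.0
DEFAULT_WINDOW = (10.0, 70.0)  # cm^-1, where the reduced approximation holds
DEFAULT_TOL_NEG = 0.05  # tolerated negative-loss excursion from noisy inputs
_SINGULAR = 1e-12  # relative scale below which a denominator counts as singular


class EffectiveMediumError(ValueError):
    """Raised for invalid mixing inputs or unsolvable configurations."""


# ---------------------------------------------------------------------------
# two-phase Bruggeman


def bruggeman2_residual(eps_a, eps_b, eps_e, f_a):
    """Two-phase Bruggeman balance evaluated at a trial effective value.

    f_a (eps_a - eps_e)/(eps_a + 2 eps_e)
      + (1 - f_a)(eps_b - eps_e)/(eps_b + 2 eps_e).
    Zero exactly when ``eps_e`` is the effective permittivity of the
    mixture; antisymmetric under swapping phases together with
    ``f_a -> 1 - f_a``.
    """
    eps_a = np.asarray(eps_a, dtype=complex)
    eps_b = np.asarray(eps_b, dtype=complex)
    eps_e = np.asarray(eps_e, dtype=complex)
    da = eps_a + 2 * eps_e
    db = eps_b + 2 * eps_e
    scale = np.maximum(np.abs(eps_a), np.abs(eps_e)) + np.maximum(
        np.abs(eps_b), np.abs(eps_e)
    )
    if np.any(np.abs(da) <= _SINGULAR * scale) or np.any(
        np.abs(db) <= _SINGULAR * scale
    ):
        raise EffectiveMediumError("singular denominator in two-phase residual")
    return f_a * (eps_a - eps_e) / da + (1 - f_a) * (eps_b - eps_e) / db


def _pick_physical_root(roots: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Choose, per frequency, the passive root closest to ``reference``.

    ``roots`` has shape (n_roots, n_freq).  Passivity (Im >= -tiny) is a
    hard preference; among qualifying roots the one nearest the reference
    wins.  Where no root is passive the nearest root is returned anyway —
    callers that need strictness check afterwards.
    """
    tiny = 1e-9 * (1.0 + np.abs(reference))
    penalty = np.where(roots.imag >= -tiny, 0.0, 1e6 * (1.0 + np.abs(roots)))
    score = np.abs(roots - reference) + penalty
    idx = np.argmin(score, axis=0)
    return np.take_along_axis(roots, idx[None, :], axis=0)[0]


def bruggeman2_effective(eps_a, eps_b, f_a):
    """Effective permittivity of a two-phase Bruggeman mixture.

    Solves 2 x^2 - b x - eps_a eps_b = 0 with
    b = f_a (2 eps_a - eps_b) + (1 - f_a)(2 eps_b - eps_a), keeping the
    passive branch.  For real positive inputs the result obeys the Wiener
    bounds min(eps_a, eps_b) <= eps_e <= max(eps_a, eps_b).
    """
    eps_a = np.atleast_1d(np.asarray(eps_a, dtype=complex))
    eps_b = np.atleast_1d(np.asarray(eps_b, dtype=complex))
    eps_a, eps_b = np.broadcast_arrays(eps_a, eps_b)
    b = f_a * (2 * eps_a - eps_b) + (1 - f_a) * (2 * eps_b - eps_a)
    disc = np.sqrt(b * b + 8 * eps_a * eps_b)
    roots = np.stack([(b + disc) / 4.0, (b - disc) / 4.0])
    linear = f_a * eps_a + (1 - f_a) * eps_b
    out = _pick_physical_root(roots, linear)
    res = bruggeman2_residual(eps_a, eps_b, out, f_a)
    if np.any(np.abs(res) > 1e-8):
        raise EffectiveMediumError(
            "two-phase forward solve failed its residual check"
        )
    return out if out.shape else out[()]


def shell_from_concentrated(eps_p, eps_cs, f_p):
    """Shell permittivity from the concentrated-solution two-phase balance.

    eps_sh = [(1 - 3 f_p) eps_p eps_cs + 2 eps_cs^2]
             / [eps_p + (2 - 3 f_p) eps_cs].
    Substituting (eps_p, eps_sh, eps_cs, f_p) back into the two-phase
    residual gives zero identically.
    """
    eps_p = np.asarray(eps_p, dtype=complex)
    eps_cs = np.asarray(eps_cs, dtype=complex)
    num = (1 - 3 * f_p) * eps_p * eps_cs + 2 * eps_cs**2
    den = eps_p + (2 - 3 * f_p) * eps_cs
    scale = np.abs(eps_p) + np.abs(eps_cs)
    if np.any(np.abs(den) <= _SINGULAR * scale):
        raise EffectiveMediumError(
            "singular denominator expressing the shell permittivity"
        )
    return num / den


def protein_from_shell(eps_sh, eps_cs, f_p):
    """Invert :func:`shell_from_concentrated` for the protein permittivity.

    eps_p = eps_cs [2 eps_cs - (2 - 3 f_p) eps_sh]
            / [eps_sh - (1 - 3 f_p) eps_cs].
    """
    eps_sh = np.asarray(eps_sh, dtype=complex)
    eps_cs = np.asarray(eps_cs, dtype=complex)
    den = eps_sh - (1 - 3 * f_p) * eps_cs
    scale = np.abs(eps_sh) + np.abs(eps_cs)
    if np.any(np.abs(den) <= _SINGULAR * scale):
        raise EffectiveMediumError(
            "singular denominator inverting the shell relation"
        )
    return eps_cs * (2 * eps_cs - (2 - 3 * f_p) * eps_sh) / den


# ---------------------------------------------------------------------------
# three-phase Bruggeman


def bruggeman3_residual(eps_p, eps_sh, eps_w, eps_s, f, f_sh):
    """Three-phase Bruggeman balance at a trial dilute-solution value."""
    eps_p = np.asarray(eps_p, dtype=complex)
    eps_sh = np.asarray(eps_sh, dtype=complex)
    eps_w = np.asarray(eps_w, dtype=complex)
    eps_s = np.asarray(eps_s, dtype=complex)
    terms = []
    for eps_i, f_i in ((eps_p, f), (eps_sh, f_sh), (eps_w, 1 - f - f_sh)):
        den = eps_i + 2 * eps_s
        scale = np.abs(eps_i) + np.abs(eps_s)
        if np.any(np.abs(den) <= _SINGULAR * scale):
            raise EffectiveMediumError("singular denominator in three-phase residual")
        terms.append(f_i * (eps_i - eps_s) / den)
    return terms[0] + terms[1] + terms[2]


def bruggeman3_effective(eps_p, eps_sh, eps_w, f, f_sh):
    """Effective permittivity of the three-phase mixture (cubic solve).

    Clearing the three denominators leaves a cubic in the effective value;
    roots are found per frequency and the passive root nearest the
    volume-weighted linear mixture is returned.
    """
    eps_p = np.atleast_1d(np.asarray(eps_p, dtype=complex))
    eps_sh = np.atleast_1d(np.asarray(eps_sh, dtype=complex))
    eps_w = np.atleast_1d(np.asarray(eps_w, dtype=complex))
    eps_p, eps_sh, eps_w = np.broadcast_arrays(eps_p, eps_sh, eps_w)
    f_w = 1 - f - f_sh
    linear = f * eps_p + f_sh * eps_sh + f_w * eps_w

    out = np.empty_like(eps_p)
    for k in range(eps_p.size):
        a, b, c = eps_p.flat[k], eps_sh.flat[k], eps_w.flat[k]
        # weight_i * (eps_i - x) * prod_{j != i} (eps_j + 2 x), descending coeffs
        poly = (
            f * np.polymul([-1, a], np.polymul([2, b], [2, c]))
            + f_sh * np.polymul([-1, b], np.polymul([2, a], [2, c]))
            + f_w * np.polymul([-1, c], np.polymul([2, a], [2, b]))
        )
        roots = np.roots(poly)
        out.flat[k] = _pick_physical_root(
            roots[:, None], np.atleast_1d(linear.flat[k])
        )[0]
    res = bruggeman3_residual(eps_p, eps_sh, eps_w, out, f, f_sh)
    if np.any(np.abs(res) > 1e-8):
        raise EffectiveMediumError(
            "three-phase forward solve failed its residual check"
        )
    return out if out.shape else out[()]


# ---------------------------------------------------------------------------
# the combined equation in eps_p and its two solvers


def full_residual(eps_p, eps_w, eps_s, eps_cs, fractions: PhaseFractions):
    """The combined per-frequency equation, term by term.

    Returns ``(total, (T1, T2, T3))`` where T1 is the protein term of the
    three-phase balance, T2 the shell term with the shell expressed through
    the concentrated solution, and T3 the bulk-water term.  A solution of
    the combined equation drives ``total`` to zero.
    """
    eps_p = np.asarray(eps_p, dtype=complex)
    eps_w = np.asarray(eps_w, dtype=complex)
    eps_s = np.asarray(eps_s, dtype=complex)
    eps_cs = np.asarray(eps_cs, dtype=complex)
    f, f_sh, f_p = fractions.f, fractions.f_sh, fractions.f_p
    eps_sh = shell_from_concentrated(eps_p, eps_cs, f_p)
    t1 = f * (eps_p - eps_s) / (eps_p + 2 * eps_s)
    t2 = f_sh * (eps_sh - eps_s) / (eps_sh + 2 * eps_s)
    t3 = (1 - f - f_sh) * (eps_w - eps_s) / (eps_w + 2 * eps_s)
    return t1 + t2 + t3, (t1, t2, t3)


def _poly_and_scales(eps_w, eps_s, eps_cs, fractions: PhaseFractions):
    eps_w = np.atleast_1d(np.asarray(eps_w, dtype=complex))
    eps_s = np.atleast_1d(np.asarray(eps_s, dtype=complex))
    eps_cs = np.atleast_1d(np.asarray(eps_cs, dtype=complex))
    f, f_sh, f_p = fractions.f, fractions.f_sh, fractions.f_p

    n1 = (1 - 3 * f_p) * eps_cs
    n0 = 2 * eps_cs**2
    d1 = np.ones_like(eps_cs)
    d0 = (2 - 3 * f_p) * eps_cs
    # A = N + 2 eps_s D (denominator of T2), B = N - eps_s D (numerator of T2)
    a1, a0 = n1 + 2 * eps_s * d1, n0 + 2 * eps_s * d0
    b1, b0 = n1 - eps_s * d1, n0 - eps_s * d0
    k = (1 - f - f_sh) * (eps_w - eps_s) / (eps_w + 2 * eps_s)

    # f (x - eps_s) A + f_sh B (x + 2 eps_s) + K (x + 2 eps_s) A
    t2_parts = (f * a1, f_sh * b1, k * a1)
    t1_parts = (
        f * (a0 - eps_s * a1),
        f_sh * (b0 + 2 * eps_s * b1),
        k * (a0 + 2 * eps_s * a1),
    )
    t0_parts = (f * (-eps_s * a0), f_sh * (2 * eps_s * b0), k * (2 * eps_s * a0))
    coeffs = np.stack([sum(t2_parts), sum(t1_parts), sum(t0_parts)])
    # magnitude of the addends before cancellation: a coefficient far below
    # its scale is a numerical zero, not a small coefficient
    scales = np.stack(
        [sum(np.abs(p) for p in parts) for parts in (t2_parts, t1_parts, t0_parts)]
    )
    return coeffs, scales


def full_polynomial_coefficients(eps_w, eps_s, eps_cs, fractions: PhaseFractions):
    """Coefficients (descending) of the cleared-denominator combined equation.

    With N(x) = (1 - 3 f_p) eps_cs x + 2 eps_cs^2 and
    D(x) = x + (2 - 3 f_p) eps_cs the shell is N/D; multiplying the
    combined equation by (x + 2 eps_s)(N + 2 eps_s D) clears both
    x-dependent denominators and leaves a quadratic in x = eps_p.
    Returns an array of shape (3, n_freq).
    """
    coeffs, _ = _poly_and_scales(eps_w, eps_s, eps_cs, fractions)
    return coeffs


def solve_protein_reduced(eps_w, eps_s, eps_cs, fractions: PhaseFractions):
    """Linear (reduced) solve of the combined equation, neglecting T1.

    Setting T2 = -T3 gives the shell contrast directly:
    C = -(1 - f - f_sh)(eps_w - eps_s) / [(eps_w + 2 eps_s) f_sh],
    eps_sh = eps_s (1 + 2C) / (1 - C), and the two-phase closed form is
    inverted for eps_p.  The solution is unique — no branch choice — which
    is what makes it robust to measurement-scale input errors.
    """
    eps_w = np.asarray(eps_w, dtype=complex)
    eps_s = np.asarray(eps_s, dtype=complex)
    eps_cs = np.asarray(eps_cs, dtype=complex)
    f, f_sh = fractions.f, fractions.f_sh
    if f_sh <= 0:
        raise EffectiveMediumError("reduced solver requires f_sh > 0")
    c = -(1 - f - f_sh) * (eps_w - eps_s) / ((eps_w + 2 * eps_s) * f_sh)
    one_minus = 1 - c
    if np.any(np.abs(one_minus) <= _SINGULAR):
        raise EffectiveMediumError("shell contrast C = 1: reduced solve singular")
    eps_sh = eps_s * (1 + 2 * c) / one_minus
    return protein_from_shell(eps_sh, eps_cs, fractions.f_p)


def solve_protein_full(
    eps_w,
    eps_s,
    eps_cs,
    fractions: PhaseFractions,
    hint=None,
    continuity: bool = True,
):
    """Quadratic (full) solve of the combined equation.

    Both roots of the cleared-denominator quadratic are computed per
    frequency.  Selection: passive roots (eps'' above a small negative
    tolerance) are preferred; among candidates the root nearest ``hint``
    (default: the reduced solution) wins; with ``continuity`` the previous
    frequency's choice replaces the hint once a root has been accepted,
    which keeps noiseless spectra on one branch.

    Both roots are exact solutions of the combined equation, so when the
    protein contrast against the solution is large — where the reduced
    hint is badly biased — selection may land on the conjugate branch;
    supply ``hint`` from prior knowledge in that regime.  A degenerate
    case exists: when all three measured spectra coincide and the
    fractions are concentration-consistent (f (1 - f_p) = f_p f_sh), the
    equation is satisfied identically and the hint is returned.

    Returns ``(eps_p, meta)`` where ``meta`` maps ``"n_physical"``,
    ``"root_index"`` and ``"residual"`` to per-frequency arrays.
    """
    eps_w = np.atleast_1d(np.asarray(eps_w, dtype=complex))
    eps_s = np.atleast_1d(np.asarray(eps_s, dtype=complex))
    eps_cs = np.atleast_1d(np.asarray(eps_cs, dtype=complex))
    eps_w, eps_s, eps_cs = np.broadcast_arrays(eps_w, eps_s, eps_cs)
    if hint is None:
        hint = solve_protein_reduced(eps_w, eps_s, eps_cs, fractions)
    hint = np.broadcast_to(np.asarray(hint, dtype=complex), eps_w.shape)

    coeffs, scales = _poly_and_scales(eps_w, eps_s, eps_cs, fractions)
    m = eps_w.size
    out = np.empty(m, dtype=complex)
    n_physical = np.zeros(m, dtype=int)
    root_index = np.full(m, -1, dtype=int)
    residual = np.full(m, np.nan)
    prev: Optional[complex] = None

    for k in range(m):
        c2, c1, c0 = coeffs[:, k]
        s2, s1, s0 = scales[:, k]
        if (
            abs(c2) <= 1e-9 * s2
            and abs(c1) <= 1e-9 * s1
            and abs(c0) <= 1e-9 * s0
        ):
            # polynomial vanished by cancellation: the equation is satisfied
            # identically and carries no information; keep the hint
            out[k] = hint[k]
            residual[k] = 0.0
            continue
        scale = max(abs(c2), abs(c1), abs(c0))
        if abs(c2) <= _SINGULAR * scale:
            roots = np.array([-c0 / c1])
        else:
            disc = np.sqrt(c1 * c1 - 4 * c2 * c0)
            roots = np.array([(-c1 + disc) / (2 * c2), (-c1 - disc) / (2 * c2)])
        tiny = 1e-9 * (1.0 + np.abs(roots))
        physical = roots.imag >= -tiny
        n_physical[k] = int(physical.sum())
        ref = prev if (continuity and prev is not None) else hint[k]
        candidates = roots[physical] if physical.any() else roots
        cand_idx = np.flatnonzero(physical) if physical.any() else np.arange(roots.size)
        j = int(np.argmin(np.abs(candidates - ref)))
        out[k] = candidates[j]
        root_index[k] = int(cand_idx[j])
        total, (t1, t2, t3) = full_residual(
            out[k], eps_w[k], eps_s[k], eps_cs[k], fractions
        )
        tmax = max(abs(t1), abs(t2), abs(t3), 1e-300)
        residual[k] = abs(total) / tmax
        if physical.any():
            prev = out[k]

    meta = {"n_physical": n_physical, "root_index": root_index, "residual": residual}
    return out, meta


def term_magnitudes(eps_p, eps_w, eps_s, eps_cs, fractions: PhaseFractions, ratio: float = DEFAULT_VALIDITY_RATIO):
    """Magnitudes |T1|, |T2|, |T3| of the combined equation plus validity.

    A frequency is valid when both |T2| >= ratio * |T1| and
    |T3| >= ratio * |T1| — the neglected protein term really is small
    compared to the terms retained by the reduced solver.
    """
    _, (t1, t2, t3) = full_residual(eps_p, eps_w, eps_s, eps_cs, fractions)
    a1, a2, a3 = np.abs(t1), np.abs(t2), np.abs(t3)
    valid = (a2 >= ratio * a1) & (a3 >= ratio * a1)
    return (a1, a2, a3), valid


# ---------------------------------------------------------------------------
# spectrum-level API


@dataclass(frozen=True, eq=False)
class SolutionTriplet:
    """Measured permittivities of solvent, dilute and concentrated solutions."""

    eps_w: DielectricSpectrum
    eps_s: DielectricSpectrum
    eps_cs: DielectricSpectrum

    def __post_init__(self) -> None:
        g = self.eps_w.grid
        if not (g.same_as(self.eps_s.grid) and g.same_as(self.eps_cs.grid)):
            raise SpectrumError(
                "solvent, dilute and concentrated spectra must share one grid; "
                "align them first"
            )

    @property
    def grid(self) -> FrequencyGrid:
        return self.eps_w.grid


@dataclass(frozen=True, eq=False)
class ExtractionResult:
    """Extracted protein spectrum with per-frequency diagnostics.

    ``valid`` combines the term-magnitude check, the frequency window, a
    solver-success flag and the negative-loss tolerance.  ``negative_loss``
    marks frequencies whose extracted loss dipped into (-tol_neg, 0): the
    values are reported as-is, never clamped.
    """

    eps_p: DielectricSpectrum
    term_magnitudes: np.ndarray  # shape (3, n_freq): |T1|, |T2|, |T3|
    valid: np.ndarray
    solver: str
    terms_ok: np.ndarray
    in_window: np.ndarray
    solver_ok: np.ndarray
    negative_loss: np.ndarray
    root_meta: dict = field(default_factory=dict)

    @property
    def grid(self) -> FrequencyGrid:
        return self.eps_p.grid


def extract_spectrum(
    triplet: SolutionTriplet,
    fractions: PhaseFractions,
    solver: str = "reduced",
    ratio: float = DEFAULT_VALIDITY_RATIO,
    window: tuple[float, float] = DEFAULT_WINDOW,
    tol_neg: float = DEFAULT_TOL_NEG,
) -> ExtractionResult:
    """Extract the protein permittivity spectrum from a solution triplet.

    Every frequency is solved (reduced solver by default); frequencies
    outside ``window`` or failing the term-magnitude ratio are flagged
    invalid but their values are retained for inspection.
    """
    if solver not in ("reduced", "full"):
        raise EffectiveMediumError(f"unknown solver {solver!r}")
    nu = triplet.grid.wavenumbers
    w, s, cs = triplet.eps_w.eps, triplet.eps_s.eps, triplet.eps_cs.eps
    m = nu.size

    eps_p = np.full(m, np.nan + 0j)
    solver_ok = np.zeros(m, dtype=bool)
    root_meta: dict = {}
    if solver == "reduced":
        for k in range(m):
            try:
                eps_p[k] = solve_protein_reduced(w[k], s[k], cs[k], fractions)
                solver_ok[k] = True
            except EffectiveMediumError:
                solver_ok[k] = False
    else:
        try:
            hint = solve_protein_reduced(w, s, cs, fractions)
        except EffectiveMediumError:
            hint = None
        values, root_meta = solve_protein_full(w, s, cs, fractions, hint=hint)
        eps_p = np.atleast_1d(values)
        solver_ok = np.isfinite(eps_p.real) & (root_meta["residual"] < 1e-6)

    mags = np.full((3, m), np.nan)
    terms_ok = np.zeros(m, dtype=bool)
    ok = solver_ok & np.isfinite(eps_p.real)
    if ok.any():
        (a1, a2, a3), t_ok = term_magnitudes(
            eps_p[ok], w[ok], s[ok], cs[ok], fractions, ratio=ratio
        )
        mags[0, ok], mags[1, ok], mags[2, ok] = a1, a2, a3
        terms_ok[ok] = t_ok

    in_window = (nu >= window[0]) & (nu <= window[1])
    negative_loss = ok & (eps_p.imag < 0) & (eps_p.imag >= -tol_neg)
    loss_ok = ok & (eps_p.imag >= -tol_neg)
    valid = solver_ok & terms_ok & in_window & loss_ok

    spectrum = DielectricSpectrum(
        grid=triplet.grid,
        eps_re=np.where(np.isfinite(eps_p.real), eps_p.real, np.nan),
        eps_im=np.where(np.isfinite(eps_p.imag), eps_p.imag, np.nan),
    )
    return ExtractionResult(
        eps_p=spectrum,
        term_magnitudes=mags,
        valid=valid,
        solver=solver,
        terms_ok=terms_ok,
        in_window=in_window,
        solver_ok=solver_ok,
        negative_loss=negative_loss,
        root_meta=root_meta,
    )


@dataclass(frozen=True, eq=False)
class SolverSpread:
    """Per-frequency spread of the extracted |eps_p| under perturbations."""

    rel_sd: np.ndarray  # SD of |eps_p| over draws / mean |eps_p|
    maxmin_ratio: np.ndarray  # max |eps_p| / min |eps_p| over draws


@dataclass(frozen=True, eq=False)
class SensitivityReport:
    """Outcome of a perturbation scan of the extraction.

    ``spreads`` maps solver name to its :class:`SolverSpread`; ``valid`` is
    the validity mask of the unperturbed reduced extraction, marking the
    frequencies on which solver comparisons are meaningful.
    """

    delta: float
    n_draws: int
    seed: int
    grid: FrequencyGrid
    spreads: dict
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.delta >= 0):
            raise EffectiveMediumError("delta must be >= 0")
        if self.n_draws < 2:
            raise EffectiveMediumError("n_draws must be >= 2")


def _perturbed_triplet(
    triplet: SolutionTriplet, rng: np.random.Generator, delta: float
) -> SolutionTriplet:
    grid = triplet.grid
    specs = []
    for spec in (triplet.eps_w, triplet.eps_s, triplet.eps_cs):
        re = spec.eps_re + rng.normal(0.0, delta, size=len(grid)) if delta else spec.eps_re
        im = spec.eps_im + rng.normal(0.0, delta, size=len(grid)) if delta else spec.eps_im
        specs.append(DielectricSpectrum(grid=grid, eps_re=re, eps_im=im))
    return SolutionTriplet(*specs)


def sensitivity_scan(
    triplet: SolutionTriplet,
    fractions: PhaseFractions,
    delta: float,
    n_draws: int,
    seed: int,
    solver: str = "both",
    ratio: float = DEFAULT_VALIDITY_RATIO,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SensitivityReport:
    """Monte-Carlo sensitivity of the extraction to input errors.

    Adds iid zero-mean Gaussian noise of standard deviation ``delta`` to
    eps' and eps'' of all three input spectra, re-extracts ``n_draws``
    times, and reports the per-frequency relative standard deviation and
    max/min ratio of |eps_p| for each requested solver.  Both solvers see
    the *same* perturbed inputs draw for draw, so their spreads are
    directly comparable.
    """
    if delta < 0:
        raise EffectiveMediumError(f"delta must be >= 0, got {delta}")
    if n_draws < 2:
        raise EffectiveMediumError(f"n_draws must be >= 2, got {n_draws}")
    solvers = ("reduced", "full") if solver == "both" else (solver,)
    for s in solvers:
        if s not in ("reduced", "full"):
            raise EffectiveMediumError(f"unknown solver {s!r}")

    rng = np.random.default_rng(seed)
    m = len(triplet.grid)
    samples = {s: np.empty((n_draws, m)) for s in solvers}
    for i in range(n_draws):
        pert = _perturbed_triplet(triplet, rng, delta)
        for s in solvers:
            res = extract_spectrum(
                pert, fractions, solver=s, ratio=ratio, window=window
            )
            samples[s][i] = np.abs(res.eps_p.eps)

    spreads = {}
    for s in solvers:
        mags = samples[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(mags, axis=0)
            sd = np.nanstd(mags, axis=0, ddof=1)
            rel_sd = np.where(mean > 0, sd / mean, np.nan)
            maxmin = np.nanmax(mags, axis=0) / np.nanmin(mags, axis=0)
        spreads[s] = SolverSpread(rel_sd=rel_sd, maxmin_ratio=maxmin)

    baseline = extract_spectrum(
        triplet, fractions, solver="reduced", ratio=ratio, window=window
    )
    return SensitivityReport(
        delta=delta,
        n_draws=n_draws,
        seed=seed,
        grid=triplet.grid,
        spreads=spreads,
        valid=baseline.valid,
    )
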