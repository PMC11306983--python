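"""Spectral containers and conversions between optical constants and permittivity.

THz time-domain spectroscopy yields, per wavenumber ``nu`` (cm^-1), the
refractive index ``n`` and the Napierian absorption coefficient ``alpha``
(cm^-1).  The complex dielectric permittivity follows from the standard
relations

    eps' = n^2 - (alpha / (4 pi nu))^2
    eps'' = n alpha / (2 pi nu)

under the ``exp(-i omega t)`` time convention, so passive media always have
``eps'' >= 0``.  This module holds the typed containers for both
representations, the exact inverse transform, delimited-text I/O, and grid
alignment by linear interpolation restricted to the common frequency
interval (never extrapolating).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "OpticalSpectrum",
    "DielectricSpectrum",
    "LayerGeometry",
    "SpectrumError",
    "absorption_from_transmission",
    "permittivity_from_optical",
    "optical_from_permittivity",
    "read_spectrum",
    "write_spectrum",
    "align_grids",
]

#: column layouts for the two on-disk dialects
DIELECTRIC_COLUMNS = ("wavenumber_cm-1", "eps_real", "eps_imag")
OPTICAL_COLUMNS = ("wavenumber_cm-1", "n", "alpha_cm-1")


class SpectrumError(ValueError):
    """Raised when spectral data violate a structural or physical invariant."""


def _as_float_array(values, name: str, allow_nan: bool = False) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SpectrumError(f"{name} must be one-dimensional, got shape {arr.shape}")
    bad_mask = np.isinf(arr) if allow_nan else ~np.isfinite(arr)
    if bad_mask.any():
        bad = int(np.flatnonzero(bad_mask)[0])
        raise SpectrumError(f"{name} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True, eq=False)
class FrequencyGrid:
    """Strictly increasing wavenumber grid in cm^-1 with at least two points."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_array(self.wavenumbers, "wavenumbers")
        if arr.size < 2:
            raise SpectrumError("a frequency grid needs at least two points")
        if np.any(arr <= 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise SpectrumError(
                f"wavenumbers must be positive; index {bad} holds {arr[bad]!r}"
            )
        if np.any(np.diff(arr) <= 0):
            bad = int(np.flatnonzero(np.diff(arr) <= 0)[0])
            raise SpectrumError(
                f"wavenumbers must be strictly increasing; violation between "
                f"indices {bad} and {bad + 1} ({arr[bad]!r} -> {arr[bad + 1]!r})"
            )
        object.__setattr__(self, "wavenumbers", arr)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def same_as(self, other: "FrequencyGrid", rtol: float = 1e-12) -> bool:
        return len(self) == len(other) and np.allclose(
            self.wavenumbers, other.wavenumbers, rtol=rtol, atol=0.0
        )


@dataclass(frozen=True, eq=False)
class LayerGeometry:
    """A single homogeneous layer of thickness ``d`` (cm)."""

    thickness_cm: float

    def __post_init__(self) -> None:
        if not (self.thickness_cm > 0):
            raise SpectrumError(f"layer thickness must be > 0, got {self.thickness_cm}")

    @classmethod
    def from_um(cls, thickness_um: float) -> "LayerGeometry":
        return cls(thickness_cm=thickness_um * 1e-4)


@dataclass(frozen=True, eq=False)
class OpticalSpectrum:
    """Refractive index ``n`` and absorption ``alpha`` (cm^-1, natural log) per frequency."""

    grid: FrequencyGrid
    n: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        n = _as_float_array(self.n, "n")
        alpha = _as_float_array(self.alpha, "alpha")
        m = len(self.grid)
        if n.size != m or alpha.size != m:
            raise SpectrumError(
                f"grid has {m} points but n has {n.size} and alpha has {alpha.size}"
            )
        if np.any(n <= 0):
            bad = int(np.flatnonzero(n <= 0)[0])
            raise SpectrumError(f"refractive index must be > 0; index {bad}: {n[bad]!r}")
        if np.any(alpha < 0):
            bad = int(np.flatnonzero(alpha < 0)[0])
            raise SpectrumError(
                f"absorption coefficient must be >= 0; index {bad}: {alpha[bad]!r}"
            )
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "alpha", alpha)


@dataclass(frozen=True, eq=False)
class DielectricSpectrum:
    """Complex permittivity ``eps* = eps' + i eps''`` per frequency.

    ``eps_im >= 0`` is the passive branch; containers may hold slightly
    negative loss produced by noisy inversions, so the constructor accepts
    any finite values and physicality is checked where it matters.  NaN is
    admitted as the marker for a frequency where an inversion failed.
    """

    grid: FrequencyGrid
    eps_re: np.ndarray
    eps_im: np.ndarray

    def __post_init__(self) -> None:
        re = _as_float_array(self.eps_re, "eps_re", allow_nan=True)
        im = _as_float_array(self.eps_im, "eps_im", allow_nan=True)
        m = len(self.grid)
        if re.size != m or im.size != m:
            raise SpectrumError(
                f"grid has {m} points but eps_re has {re.size} and eps_im has {im.size}"
            )
        object.__setattr__(self, "eps_re", re)
        object.__setattr__(self, "eps_im", im)

    @property
    def eps(self) -> np.ndarray:
        """Complex permittivity array."""
        return self.eps_re + 1j * self.eps_im

    @classmethod
    def from_complex(cls, grid: FrequencyGrid, eps: np.ndarray) -> "DielectricSpectrum":
        eps = np.asarray(eps, dtype=complex)
        return cls(grid=grid, eps_re=eps.real.copy(), eps_im=eps.imag.copy())


Spectrum = Union[OpticalSpectrum, DielectricSpectrum]


def absorption_from_transmission(
    tr: Sequence[float] | np.ndarray, geom: LayerGeometry
) -> np.ndarray:
    """Napierian absorption coefficient alpha = -ln(Tr)/d in cm^-1.

    ``Tr`` is the internal transmittance of a layer of thickness ``d``
    (cm); values must lie in (0, 1].
    """
    tr = _as_float_array(tr, "transmittance")
    bad = np.flatnonzero((tr <= 0) | (tr > 1))
    if bad.size:
        i = int(bad[0])
        raise SpectrumError(
            f"transmittance must lie in (0, 1]; index {i} holds {tr[i]!r}"
        )
    alpha = -np.log(tr) / geom.thickness_cm
    # ln(1) can round to -0.0; report exact zero there
    alpha[tr == 1.0] = 0.0
    return alpha


def permittivity_from_optical(opt: OpticalSpectrum) -> DielectricSpectrum:
    """Convert (n, alpha) to complex permittivity.

    eps' = n^2 - (alpha/(4 pi nu))^2 and eps'' = n alpha / (2 pi nu), with
    both nu and alpha in cm^-1 so the extinction ratio is dimensionless.
    """
    nu = opt.grid.wavenumbers
    kappa = opt.alpha / (4.0 * np.pi * nu)
    eps_re = opt.n**2 - kappa**2
    eps_im = 2.0 * opt.n * kappa
    return DielectricSpectrum(grid=opt.grid, eps_re=eps_re, eps_im=eps_im)


def optical_from_permittivity(diel: DielectricSpectrum) -> OpticalSpectrum:
    """Exact inverse of :func:`permittivity_from_optical` on the passive branch.

    n = sqrt((|eps*| + eps')/2), kappa = sqrt((|eps*| - eps')/2),
    alpha = 4 pi nu kappa.  Requires eps'' >= 0; a negative-loss input has
    no passive optical-constant representation and is rejected.
    """
    if np.any(diel.eps_im < 0):
        bad = int(np.flatnonzero(diel.eps_im < 0)[0])
        raise SpectrumError(
            f"eps_im must be >= 0 for optical constants; index {bad}: "
            f"{diel.eps_im[bad]!r}"
        )
    mod = np.hypot(diel.eps_re, diel.eps_im)
    n = np.sqrt(np.maximum(mod + diel.eps_re, 0.0) / 2.0)
    kappa = np.sqrt(np.maximum(mod - diel.eps_re, 0.0) / 2.0)
    # mod -/+ eps_re cancels catastrophically when |eps''| << |eps'|; the
    # exact identity eps'' = 2 n kappa recovers the small factor stably
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(diel.eps_re >= 0, diel.eps_im / (2.0 * n), kappa)
        n = np.where(
            (diel.eps_re < 0) & (kappa > 0), diel.eps_im / (2.0 * kappa), n
        )
    kappa = np.where(np.isfinite(kappa), kappa, 0.0)
    alpha = 4.0 * np.pi * diel.grid.wavenumbers * kappa
    return OpticalSpectrum(grid=diel.grid, n=n, alpha=alpha)


def read_spectrum(path: str | Path, dialect: str = "auto") -> Spectrum:
    """Read a spectrum from a delimited text file.

    Two header dialects are recognised: ``wavenumber_cm-1,eps_real,eps_imag``
    (dielectric) and ``wavenumber_cm-1,n,alpha_cm-1`` (optical).  Lines
    starting with ``#`` are comments.  ``dialect`` may be ``"auto"``,
    ``"dielectric"`` or ``"optical"``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectrumError(f"{path}: cannot parse as delimited text: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    cols = set(df.columns)

    if dialect == "auto":
        if set(DIELECTRIC_COLUMNS) <= cols:
            dialect = "dielectric"
        elif set(OPTICAL_COLUMNS) <= cols:
            dialect = "optical"
        else:
            raise SpectrumError(
                f"{path}: header {sorted(cols)} matches neither the dielectric "
                f"dialect {DIELECTRIC_COLUMNS} nor the optical dialect "
                f"{OPTICAL_COLUMNS}"
            )
    wanted = DIELECTRIC_COLUMNS if dialect == "dielectric" else OPTICAL_COLUMNS
    missing = [c for c in wanted if c not in cols]
    if missing:
        raise SpectrumError(f"{path}: missing column(s) {missing}")

    data = {}
    for c in wanted:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise SpectrumError(
                f"{path}: non-numeric cell in column {c!r}, data row {row}"
            )
        data[c] = col.to_numpy(dtype=float)

    grid = FrequencyGrid(data[wanted[0]])
    if dialect == "dielectric":
        return DielectricSpectrum(grid=grid, eps_re=data["eps_real"], eps_im=data["eps_imag"])
    return OpticalSpectrum(grid=grid, n=data["n"], alpha=data["alpha_cm-1"])


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the matching CSV dialect (UTF-8, header row)."""
    path = Path(path)
    if isinstance(spec, DielectricSpectrum):
        df = pd.DataFrame(
            {
                "wavenumber_cm-1": spec.grid.wavenumbers,
                "eps_real": spec.eps_re,
                "eps_imag": spec.eps_im,
            }
        )
    elif isinstance(spec, OpticalSpectrum):
        df = pd.DataFrame(
            {
                "wavenumber_cm-1": spec.grid.wavenumbers,
                "n": spec.n,
                "alpha_cm-1": spec.alpha,
            }
        )
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialise {type(spec).__name__}")
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _interp_onto(values: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return np.interp(dst, src, values)


def align_grids(*spectra: Spectrum) -> tuple[Spectrum, ...]:
    """Bring spectra onto a common grid by linear interpolation.

    The target grid is restricted to the overlap of all input intervals —
    values are only ever interpolated, never extrapolated.  Among the
    inputs, the coarsest grid (fewest points inside the overlap) supplies
    the target points, so a spectrum sampled on a subset grid is left
    untouched and the others are interpolated onto it.
    """
    if not spectra:
        raise SpectrumError("align_grids needs at least one spectrum")
    lo = max(s.grid.wavenumbers[0] for s in spectra)
    hi = min(s.grid.wavenumbers[-1] for s in spectra)
    if not (lo < hi):
        raise SpectrumError(
            f"frequency grids do not overlap (common interval [{lo}, {hi}])"
        )
    candidates = []
    for s in spectra:
        w = s.grid.wavenumbers
        candidates.append(w[(w >= lo) & (w <= hi)])
    target = min(candidates, key=len)
    if target.size < 2:
        raise SpectrumError(
            "overlap contains fewer than two grid points; cannot align"
        )
    grid = FrequencyGrid(target)

    out: list[Spectrum] = []
    for s in spectra:
        w = s.grid.wavenumbers
        if isinstance(s, DielectricSpectrum):
            out.append(
                DielectricSpectrum(
                    grid=grid,
                    eps_re=_interp_onto(s.eps_re, w, target),
                    eps_im=_interp_onto(s.eps_im, w, target),
                )
            )
        else:
            out.append(
                OpticalSpectrum(
                    grid=grid,
                    n=_interp_onto(s.n, w, target),
                    alpha=_interp_onto(s.alpha, w, target),
                )
            )
    return tuple(out)
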