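"""SAXS profile averaging, scale/offset fitting and RMSE scoring.

Per-frame intensity computation (e.g. crysol with an explicit hydration
shell) is consumed, not re-implemented: this module reads crysol .int/.fit
files and generic ``q I [sigma]`` text, averages per-frame profiles, fits
the ensemble-average curve to experiment as

    I_fit(q) = scale · I_comp(q) + offset

inside a q-window (default 0.01–0.3, in the input q units), min-max
normalizes profiles for comparative plots, and scores agreement by RMSE.
The scale/offset model is linear in its parameters, so the
Levenberg–Marquardt fit converges to the ordinary linear least-squares
solution; it is implemented in closed form.

A coarse Debye-formula calculator over Cα pseudo-atoms is provided only so
tests can run self-contained; it ignores solvent and atomic form factors
and is not quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import FormatError, GridMismatchError

__all__ = [
    "SAXSProfile",
    "SAXSFitResult",
    "read_saxs",
    "read_crysol_int",
    "write_saxs",
    "average_profiles",
    "fit_scale_offset",
    "normalize_profile",
    "profile_rmse",
    "debye_profile_ca",
]


@dataclass(frozen=True)
class SAXSProfile:
    """A scattering curve: q (strictly increasing, ≥ 0), intensity, σ."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if q.ndim != 1 or q.shape != i.shape:
            raise ValueError("q and intensity must be 1-D of equal length")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be non-negative, strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ValueError("sigma must match q")
            object.__setattr__(self, "sigma", s)


@dataclass
class SAXSFitResult:
    """Outcome of fitting a computed profile to experiment."""

    scale: float
    offset: float
    fitted: SAXSProfile
    normalized_exp: SAXSProfile
    normalized_fit: SAXSProfile
    rmse: float
    rmse_normalized: float


def read_saxs(path: str | Path) -> SAXSProfile:
    """Read generic 2–3 column ``q I [sigma]`` text ('#'/'@' comments)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.split()
        try:
            rows.append([float(x) for x in parts[:3]])
        except ValueError as exc:
            raise FormatError(f"{path}: bad data line {s!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows])
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSProfile(q=arr[:, 0], intensity=arr[:, 1], sigma=sigma)


def read_crysol_int(path: str | Path) -> SAXSProfile:
    """Read a crysol 3.x .int/.fit file (title line + numeric columns).

    The first two numeric columns are q and the total intensity in vacuo +
    shell (crysol's I_total); extra columns are ignored.
    """
    lines = Path(path).read_text().splitlines()
    rows = []
    for line in lines:
        parts = line.split()
        if len(parts) < 2:
            continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            continue  # title/header line
    if not rows:
        raise FormatError(f"{path}: no numeric rows found")
    arr = np.array(rows)
    return SAXSProfile(q=arr[:, 0], intensity=arr[:, 1])


def write_saxs(profile: SAXSProfile, path: str | Path) -> None:
    """Write a ``# q I [sigma]`` text profile."""
    cols = [profile.q, profile.intensity]
    header = "# q I"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    lines = [header] + [
        " ".join(f"{v:.17g}" for v in row) for row in zip(*cols)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def average_profiles(per_frame: Sequence[SAXSProfile]) -> SAXSProfile:
    """Pointwise mean intensity of profiles sharing one q grid."""
    if len(per_frame) == 0:
        raise ValueError("no profiles to average")
    q = per_frame[0].q
    for p in per_frame[1:]:
        if p.q.shape != q.shape or not np.array_equal(p.q, q):
            raise GridMismatchError("profiles are not on an identical q grid")
    mean_i = np.mean([p.intensity for p in per_frame], axis=0)
    return SAXSProfile(q=q, intensity=mean_i)


def fit_scale_offset(
    computed: SAXSProfile,
    experimental: SAXSProfile,
    qmin: float = 0.01,
    qmax: float = 0.3,
    rmse_on_normalized: bool = False,
) -> SAXSFitResult:
    """Fit I_fit = scale·I_comp + offset to experiment inside [qmin, qmax].

    The computed profile is linearly interpolated onto the experimental q
    points inside the window; points outside never influence the fit.  The
    reported RMSE compares experiment with the fitted curve on the raw
    intensity scale by default (``rmse_on_normalized=True`` computes it on
    the min-max normalized curves instead); both values are returned.
    """
    window = (experimental.q >= qmin) & (experimental.q <= qmax)
    q = experimental.q[window]
    if q.size < 2:
        raise ValueError(
            f"fewer than two experimental q points inside [{qmin}, {qmax}]"
        )
    i_exp = experimental.intensity[window]
    i_comp = np.interp(q, computed.q, computed.intensity)

    design = np.column_stack([i_comp, np.ones_like(i_comp)])
    (scale, offset), *_ = np.linalg.lstsq(design, i_exp, rcond=None)

    i_fit = scale * i_comp + offset
    fitted = SAXSProfile(q=q, intensity=i_fit)
    exp_win = SAXSProfile(q=q, intensity=i_exp)
    norm_exp = normalize_profile(exp_win)
    norm_fit = normalize_profile(fitted)
    rmse_raw = profile_rmse(exp_win, fitted)
    rmse_norm = profile_rmse(norm_exp, norm_fit)
    return SAXSFitResult(
        scale=float(scale),
        offset=float(offset),
        fitted=fitted,
        normalized_exp=norm_exp,
        normalized_fit=norm_fit,
        rmse=rmse_norm if rmse_on_normalized else rmse_raw,
        rmse_normalized=rmse_norm,
    )


def normalize_profile(profile: SAXSProfile) -> SAXSProfile:
    """Min-max normalization: (I − I_min) / (I_max − I_min)."""
    i = profile.intensity
    lo, hi = i.min(), i.max()
    if hi == lo:
        raise ValueError("constant profile cannot be min-max normalized")
    return SAXSProfile(q=profile.q, intensity=(i - lo) / (hi - lo))


def profile_rmse(exp: SAXSProfile, fit: SAXSProfile) -> float:
    """RMSE = sqrt(mean (I_exp − I_fit)²) on a shared q grid."""
    if exp.q.shape != fit.q.shape or not np.allclose(exp.q, fit.q):
        raise GridMismatchError("profiles are not on the same q grid")
    return float(np.sqrt(np.mean((exp.intensity - fit.intensity) ** 2)))


def debye_profile_ca(coords_nm: np.ndarray, q: np.ndarray) -> SAXSProfile:
    """Coarse Debye-formula intensity over Cα pseudo-atoms (tests only).

    I(q) = Σ_ij sinc(q r_ij) with unit form factors; q in nm⁻¹ matching
    the coordinate units.  Not quantitative: no solvent, no form factors.
    """
    x = np.asarray(coords_nm, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
    qr = q[:, None, None] * d[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(qr == 0.0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
    return SAXSProfile(q=q, intensity=s.sum(axis=(1, 2)))
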