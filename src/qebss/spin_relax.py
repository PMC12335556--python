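"""Backbone ¹⁵N spin-relaxation physics.

The chain implemented here is the standard route from an MD trajectory to
NMR observables:

1.  The second-order (P2) rotational autocorrelation function of each
    backbone N–H bond vector, g(t) = ⟨3/2 cos²θ(t) − 1/2⟩, averaged over
    all time origins.
2.  A fit of g(t) to a sum of exponential decays on a fixed grid of
    timescales τ_i equidistant in log-space (default 100 points between
    1 ps and 100 ns), with non-negative weights α_i solved by NNLS:
    C_fit(t) = Σ α_i exp(−t/τ_i).
3.  The analytical spectral density of that fit,
    J(ω) = Σ α_i · 2τ_i / (1 + (ωτ_i)²),
    evaluated at the Larmor frequency combinations.
4.  Redfield expressions for 1/T1, 1/T2 and hetNOE combining the ¹H–¹⁵N
    dipolar coupling and the ¹⁵N chemical-shift-anisotropy (CSA)
    mechanisms.

Convention notes.  The J(ω) normalization above is the one under which the
d²_NH/20 dipolar prefactors in the rate expressions reproduce standard
Redfield rates; it is cross-checked against an independent closed-form
Lorentzian implementation in the test suite.  J is even, so magnitudes of
frequency combinations are used (ω_N < 0 because γ_N < 0).  The hetNOE
cross-relaxation term defaults to the standard sign,
σ ∝ 6J(ω_H+ω_N) − J(ω_H−ω_N), which is the only convention that can yield
the negative hetNOE values characteristic of highly flexible residues; the
all-plus variant is available as ``noe_sign_convention="paper_plus"``.

Chemical-exchange (R_ex) contributions to T2 on µs–ms timescales are
outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.fft import next_fast_len, irfft, rfft
from scipy.optimize import nnls

from .exceptions import GridMismatchError
from .traj_io import RelaxationProfile, VectorSeries

__all__ = [
    "CorrelationFunction",
    "TimescaleGrid",
    "TimescaleSpectrum",
    "NMRParams",
    "compute_p2_acf",
    "build_timescale_grid",
    "fit_exponential_sum",
    "spectral_density",
    "relaxation_observables",
    "effective_tau",
    "average_acfs",
    "timescale_landscape",
    "predict_profile",
]

PS_TO_S = 1e-12


@dataclass(frozen=True)
class CorrelationFunction:
    """P2 orientational ACF of one residue's N–H vector.

    ``lags`` are in ps starting at 0, equally spaced; ``n_contributing``
    counts how many trajectories were averaged into the curve.
    """

    residue_id: int
    lags: np.ndarray
    values: np.ndarray
    n_contributing: int = 1

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be 1-D of equal length")
        if lags[0] != 0.0:
            raise ValueError("lags must start at 0")
        if lags.size > 1:
            d = np.diff(lags)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9):
                raise ValueError("lags must be strictly increasing, equally spaced")
        if not (0.0 < values[0] <= 1.0 + 1e-9):
            raise ValueError(f"g(0) = {values[0]} outside (0, 1]")
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    @property
    def dt(self) -> float:
        """Lag spacing in ps."""
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0


@dataclass(frozen=True)
class TimescaleGrid:
    """Fixed log-equidistant grid of correlation times, in seconds."""

    taus: np.ndarray

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if taus.ndim != 1 or taus.size < 2:
            raise ValueError("grid needs at least two timescales")
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("timescales must be positive, strictly increasing")
        ratios = np.diff(np.log(taus))
        if not np.allclose(ratios, ratios[0], atol=1e-12, rtol=0):
            raise ValueError("grid must be equidistant in log-space")
        object.__setattr__(self, "taus", taus)

    @property
    def n(self) -> int:
        return int(self.taus.size)


@dataclass(frozen=True)
class TimescaleSpectrum:
    """Non-negative weights α_i on a timescale grid (the fitted decay sum)."""

    grid: TimescaleGrid
    alphas: np.ndarray
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.shape != self.grid.taus.shape:
            raise ValueError("alphas must match the grid")
        if np.any(a < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "alphas", a)

    @property
    def total_weight(self) -> float:
        return float(self.alphas.sum())

    def evaluate(self, t_seconds: np.ndarray) -> np.ndarray:
        """C_fit(t) = Σ α_i exp(−t/τ_i) at times in seconds."""
        t = np.atleast_1d(np.asarray(t_seconds, dtype=float))
        with np.errstate(under="ignore"):
            design = np.exp(-t[:, None] / self.grid.taus[None, :])
        return design @ self.alphas


# CODATA gyromagnetic ratios, rad s^-1 T^-1 (1H and 15N).
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.71261804e7
MU0 = 4e-7 * np.pi
HBAR = 1.054571817e-34


@dataclass(frozen=True)
class NMRParams:
    """Spectrometer and spin-pair parameters for the Redfield expressions.

    ``delta_sigma_ppm`` is the ¹⁵N CSA (default −160 ppm) and ``r_nh_nm``
    the effective N–H bond length entering ⟨r³_NH⟩ (default 0.101 nm).
    """

    field_mhz: float
    delta_sigma_ppm: float = -160.0
    r_nh_nm: float = 0.101
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    n_h: int = 1
    mu0: float = MU0
    hbar: float = HBAR
    noe_sign_convention: str = "standard_minus"

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")
        if not (self.gamma_n < 0 < self.gamma_h):
            raise ValueError("expected gamma_n < 0 < gamma_h")
        if self.noe_sign_convention not in ("standard_minus", "paper_plus"):
            raise ValueError(
                f"unknown NOE sign convention {self.noe_sign_convention!r}"
            )

    @property
    def omega_h(self) -> float:
        """¹H Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """¹⁵N Larmor angular frequency, rad/s (negative: γ_N < 0)."""
        return self.omega_h * self.gamma_n / self.gamma_h

    @property
    def d_nh(self) -> float:
        """Dipolar coupling constant μ0 ħ γ_H γ_N / (4π ⟨r³_NH⟩), rad/s."""
        r_m = self.r_nh_nm * 1e-9
        return self.mu0 * self.hbar * self.gamma_h * self.gamma_n / (
            4.0 * np.pi * r_m**3
        )

    @property
    def csa_omega(self) -> float:
        """CSA interaction strength Δσ·ω_N, rad/s."""
        return self.delta_sigma_ppm * 1e-6 * self.omega_n

    def with_overrides(self, **kwargs) -> "NMRParams":
        return replace(self, **kwargs)


def compute_p2_acf(
    series: VectorSeries, max_lag_fraction: float = 0.5
) -> CorrelationFunction:
    """P2 autocorrelation of a unit-vector series, averaged over origins.

    g(τ) = ⟨ P2(v(t)·v(t+τ)) ⟩_t with P2(x) = (3x² − 1)/2.  Computed via
    FFT cross-correlations of the six independent components of the outer
    product v⊗v, which is exactly the double loop over all (t, t+τ) pairs.
    Lags extend to ``max_lag_fraction`` of the series duration.
    """
    if series.n_frames < 2:
        raise ValueError("need at least two frames for an ACF")
    if not (0.0 < max_lag_fraction <= 1.0):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    v = series.vectors
    n = v.shape[0]
    n_lags = int(np.floor(max_lag_fraction * (n - 1))) + 1

    # cos²θ(t, t+τ) = Σ_ab (v_a v_b)(t) (v_a v_b)(t+τ): correlate q_ab.
    pairs = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
             (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]
    m = next_fast_len(2 * n)
    acc = np.zeros(n_lags)
    for a, b, w in pairs:
        q = v[:, a] * v[:, b]
        fq = rfft(q, m)
        corr = irfft(fq * np.conj(fq), m)[:n_lags]
        acc += w * corr
    counts = n - np.arange(n_lags)
    g = 1.5 * acc / counts - 0.5
    lags = series.dt * np.arange(n_lags)
    return CorrelationFunction(
        residue_id=series.residue_id, lags=lags, values=g
    )


def build_timescale_grid(
    n: int = 100, tau_min: float = 1e-12, tau_max: float = 1e-7
) -> TimescaleGrid:
    """Log-equidistant timescale grid in seconds; endpoints exact.

    Defaults: 100 points spanning 1 ps to 100 ns.
    """
    if n < 2:
        raise ValueError("grid needs n >= 2")
    if not (0 < tau_min < tau_max):
        raise ValueError("need 0 < tau_min < tau_max")
    taus = np.geomspace(tau_min, tau_max, n)
    taus[0], taus[-1] = tau_min, tau_max
    return TimescaleGrid(taus=taus)


def fit_exponential_sum(
    acf: CorrelationFunction, grid: TimescaleGrid | None = None
) -> TimescaleSpectrum:
    """Fit g(t) to Σ α_i exp(−t/τ_i) with α ≥ 0 (non-negative least squares).

    No Σα = 1 constraint is imposed; g(0) = 1 keeps the total weight near
    one for properly normalized input.  ``fit_residual`` is the Euclidean
    norm of the residual vector.
    """
    if grid is None:
        grid = build_timescale_grid()
    values = np.asarray(acf.values, dtype=float)
    mask = np.isfinite(values)
    if not mask.any():
        raise ValueError("ACF is all-NaN")
    if mask.sum() < 2:
        raise ValueError("need at least two finite ACF points")
    t_s = acf.lags[mask] * PS_TO_S
    with np.errstate(under="ignore"):
        design = np.exp(-t_s[:, None] / grid.taus[None, :])
    alphas, rnorm = nnls(design, values[mask])
    return TimescaleSpectrum(grid=grid, alphas=alphas, fit_residual=float(rnorm))


def spectral_density(
    spectrum: TimescaleSpectrum, omega: float | np.ndarray
) -> float | np.ndarray:
    """J(ω) = Σ α_i · 2τ_i / (1 + (ωτ_i)²), in s/rad; even in ω."""
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    taus = spectrum.grid.taus
    j = (spectrum.alphas * 2.0 * taus / (1.0 + (w[:, None] * taus) ** 2)).sum(axis=1)
    return float(j[0]) if np.isscalar(omega) or np.ndim(omega) == 0 else j


def relaxation_observables(
    spectrum: TimescaleSpectrum, params: NMRParams
) -> tuple[float, float, float]:
    """(T1 [s], T2 [s], hetNOE) from a timescale spectrum via Redfield theory.

    Dipolar (¹H–¹⁵N) and ¹⁵N CSA mechanisms; J arguments are magnitudes of
    the Larmor-frequency combinations.
    """
    wh, wn = params.omega_h, params.omega_n
    d2 = params.d_nh**2 * params.n_h
    c2 = params.csa_omega**2

    j = {
        "hmn": spectral_density(spectrum, abs(wh - wn)),
        "n": spectral_density(spectrum, abs(wn)),
        "hpn": spectral_density(spectrum, abs(wh + wn)),
        "h": spectral_density(spectrum, abs(wh)),
        "0": spectral_density(spectrum, 0.0),
    }

    r1 = d2 / 20.0 * (j["hmn"] + 3.0 * j["n"] + 6.0 * j["hpn"]) + c2 / 15.0 * j["n"]
    r2 = 0.5 * d2 / 20.0 * (
        4.0 * j["0"] + j["hmn"] + 3.0 * j["n"] + 6.0 * j["h"] + 6.0 * j["hpn"]
    ) + c2 / 90.0 * (4.0 * j["0"] + 3.0 * j["n"])
    if r1 <= 0 or r2 <= 0:
        raise ValueError("non-positive relaxation rate: degenerate spectrum")
    t1, t2 = 1.0 / r1, 1.0 / r2

    if params.noe_sign_convention == "standard_minus":
        sigma = d2 / 20.0 * (6.0 * j["hpn"] - j["hmn"])
    else:  # paper_plus: the all-plus printed variant, kept as a flagged option
        sigma = d2 / 20.0 * (j["hmn"] + 6.0 * j["hpn"])
    hetnoe = 1.0 + sigma * params.gamma_h * t1 / params.gamma_n
    return t1, t2, hetnoe


def effective_tau(spectrum: TimescaleSpectrum) -> float:
    """Effective correlation time τ_eff = Σ α_i τ_i, in seconds.

    This is the integral of the fitted correlation function (the plain
    weighted sum, not normalized by Σα).
    """
    return float(np.dot(spectrum.alphas, spectrum.grid.taus))


def average_acfs(acfs: Sequence[CorrelationFunction]) -> CorrelationFunction:
    """Pointwise unweighted mean of same-residue ACFs.

    Inputs are truncated to the shortest common lag range; the result's
    ``n_contributing`` sums the inputs'.
    """
    if len(acfs) == 0:
        raise ValueError("no ACFs to average")
    rid = acfs[0].residue_id
    dt = acfs[0].dt
    for a in acfs[1:]:
        if a.residue_id != rid:
            raise GridMismatchError(
                f"residue mismatch: {a.residue_id} != {rid}"
            )
        if not np.isclose(a.dt, dt, rtol=1e-9):
            raise GridMismatchError("lag spacings differ")
    n = min(a.lags.size for a in acfs)
    values = np.mean([a.values[:n] for a in acfs], axis=0)
    return CorrelationFunction(
        residue_id=rid,
        lags=acfs[0].lags[:n],
        values=values,
        n_contributing=sum(a.n_contributing for a in acfs),
    )


def timescale_landscape(
    spectra: dict[int, TimescaleSpectrum] | Sequence[TimescaleSpectrum],
    bin_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin per-residue timescale weights into [edge_k, edge_{k+1}) windows.

    Returns ``(residue_ids_or_indices, weights)`` where ``weights[r, k]``
    is the summed α of residue r inside bin k.  Row sums conserve each
    spectrum's total weight, so the bin edges must span the grid.
    """
    if isinstance(spectra, dict):
        keys = np.array(sorted(spectra))
        items = [spectra[k] for k in keys]
    else:
        items = list(spectra)
        keys = np.arange(len(items))
    if not items:
        raise ValueError("no spectra given")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing, at least two")
    out = np.zeros((len(items), edges.size - 1))
    for i, sp in enumerate(items):
        taus = sp.grid.taus
        carrying = taus[sp.alphas > 0]
        if carrying.size and (
            carrying[0] < edges[0] or carrying[-1] >= edges[-1]
        ):
            raise ValueError(
                "bin edges must span every timescale carrying weight"
            )
        inside = (taus >= edges[0]) & (taus < edges[-1])
        idx = np.searchsorted(edges, taus[inside], side="right") - 1
        np.add.at(out[i], idx, sp.alphas[inside])
    return keys, out


def predict_profile(
    acfs: Sequence[CorrelationFunction],
    params: NMRParams,
    grid: TimescaleGrid | None = None,
) -> tuple[RelaxationProfile, dict[int, TimescaleSpectrum]]:
    """Fit per-residue ACFs and back-calculate a relaxation profile."""
    if grid is None:
        grid = build_timescale_grid()
    ids, t1s, t2s, noes = [], [], [], []
    spectra: dict[int, TimescaleSpectrum] = {}
    for acf in acfs:
        sp = fit_exponential_sum(acf, grid)
        t1, t2, noe = relaxation_observables(sp, params)
        ids.append(acf.residue_id)
        t1s.append(t1)
        t2s.append(t2)
        noes.append(noe)
        spectra[acf.residue_id] = sp
    order = np.argsort(ids)
    profile = RelaxationProfile(
        residue_ids=np.asarray(ids)[order],
        t1=np.asarray(t1s)[order],
        t2=np.asarray(t2s)[order],
        hetnoe=np.asarray(noes)[order],
        field_mhz=params.field_mhz,
    )
    return profile, spectra
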