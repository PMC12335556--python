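"""Synthetic fixtures with planted ground truth.

Every other module is testable offline through these generators:

* :func:`make_acf` — multi-exponential correlation functions with known
  weights (the fit's own forward model, inverted for round-trip tests);
* :func:`simulate_isotropic_rotor` — a unit vector undergoing isotropic
  rotational diffusion, whose P2 autocorrelation decays with the known
  timescale τ₂ = 1/(6·D_r);
* :func:`make_selection_fixture` — a bank of candidate "simulations" with
  distinct timescale mixtures plus an "experimental" relaxation table
  generated from one designated truth simulation through the full forward
  model (fit → Redfield), so selection must recover the planted truth;
* :func:`make_bead_ensemble` — two internally rigid bead domains joined by
  a freely jointed linker, a minimal stand-in for a multidomain protein
  with a disordered linker.

All generators take an explicit seed and derive independent per-call
random streams from it, so outputs are bit-reproducible and adding a
generator never perturbs existing fixtures.
"""

from __future__ import annotations

import numpy as np

from .spin_relax import (
    CorrelationFunction,
    NMRParams,
    TimescaleGrid,
    build_timescale_grid,
    predict_profile,
)
from .traj_io import RelaxationProfile, VectorSeries

__all__ = [
    "make_acf",
    "simulate_isotropic_rotor",
    "make_selection_fixture",
    "make_bead_ensemble",
    "fjc_mean_square_rg",
]

PS_TO_S = 1e-12

# Stream labels keep each generator's randomness independent of the others.
_STREAMS = {"acf": 1, "rotor": 2, "selection": 3, "beads": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def make_acf(
    weights: np.ndarray,
    taus_s: np.ndarray,
    time_grid_ps: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
) -> CorrelationFunction:
    """Multi-exponential ACF g(t) = Σ α e^{−t/τ} with optional Gaussian noise.

    Weights should sum to ≈1 (a normalized correlation function); noise is
    added at positive lags only so g(0) stays exact.
    """
    w = np.asarray(weights, dtype=float)
    taus = np.asarray(taus_s, dtype=float)
    t = np.asarray(time_grid_ps, dtype=float)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if np.any(taus <= 0):
        raise ValueError("timescales must be positive")
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to approximately 1")
    with np.errstate(under="ignore"):
        g = (w[None, :] * np.exp(-(t[:, None] * PS_TO_S) / taus[None, :])).sum(axis=1)
    if noise_sigma > 0:
        rng = _rng(seed, "acf")
        g[1:] = g[1:] + rng.normal(0.0, noise_sigma, size=t.size - 1)
    return CorrelationFunction(residue_id=residue_id, lags=t, values=g)


def simulate_isotropic_rotor(
    d_r: float,
    dt_ps: float,
    n_steps: int,
    seed: int = 0,
    residue_id: int = 1,
) -> VectorSeries:
    """Unit vector undergoing isotropic rotational diffusion.

    ``d_r`` is the rotational diffusion coefficient in s⁻¹; per step the
    vector is rotated by an angle sqrt(4·D_r·dt)·|N(0,1)| about a uniform
    random axis perpendicular to its current direction, giving a mean
    square angular step of 4·D_r·dt.  Valid for small steps
    (4·D_r·dt ≪ 1; a warning is issued otherwise) where the P2
    autocorrelation decays as exp(−6·D_r·t), i.e. τ₂ = 1/(6·D_r).
    """
    if d_r <= 0 or dt_ps <= 0:
        raise ValueError("d_r and dt must be positive")
    msd = 4.0 * d_r * dt_ps * PS_TO_S
    if msd > 0.1:
        import warnings

        warnings.warn(
            f"mean square step angle {msd:.3g} rad² violates the small-step "
            "assumption; the realized tau_2 may deviate from 1/(6 D_r)",
            stacklevel=2,
        )
    rng = _rng(seed, "rotor")
    angles = np.sqrt(msd) * np.abs(rng.normal(size=n_steps))
    phis = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)

    v = np.empty((n_steps + 1, 3))
    v[0] = (0.0, 0.0, 1.0)
    cur = v[0].copy()
    for k in range(n_steps):
        # orthonormal frame (e1, e2) perpendicular to the current vector
        ref = np.array([1.0, 0.0, 0.0]) if abs(cur[0]) < 0.9 else np.array(
            [0.0, 1.0, 0.0]
        )
        e1 = np.cross(cur, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(cur, e1)
        tangent = np.cos(phis[k]) * e1 + np.sin(phis[k]) * e2
        cur = np.cos(angles[k]) * cur + np.sin(angles[k]) * tangent
        cur /= np.linalg.norm(cur)
        v[k + 1] = cur
    times = dt_ps * np.arange(n_steps + 1)
    return VectorSeries(residue_id=residue_id, times=times, vectors=v)


def make_selection_fixture(
    n_sims: int = 5,
    truth_index: int = 2,
    noise_sigma: float = 0.02,
    seed: int = 0,
    n_residues: int = 5,
    field_mhz: float = 600.0,
    dt_ps: float = 50.0,
    n_lags: int = 600,
    grid: TimescaleGrid | None = None,
) -> tuple[dict[int, dict[int, CorrelationFunction]], RelaxationProfile, NMRParams]:
    """Planted-truth selection scenario.

    Each candidate simulation gets per-residue two-component ACFs whose
    fast and slow timescales both differ by simulation (20 ps × 2^s and
    1.25 ns × 2^s) and whose fast/slow weight split varies along the
    sequence — distinct dynamic landscapes, as different force fields
    would give.  Varying both components keeps the candidates separated
    in every observable (T1 alone is non-monotonic in the slow timescale,
    so a slow-timescale ladder by itself can make two candidates nearly
    degenerate in T1).  The "experimental" table is the full forward
    model (NNLS fit + Redfield) applied to the truth simulation's ACFs,
    with relative Gaussian noise ``noise_sigma`` on each observable.

    Returns ``(acf_store, experimental_profile, params)`` with
    ``acf_store[sim_id][residue_id]`` a :class:`CorrelationFunction`.
    """
    if not (0 <= truth_index < n_sims):
        raise ValueError("truth_index out of range")
    params = NMRParams(field_mhz=field_mhz)
    if grid is None:
        grid = build_timescale_grid()
    t = dt_ps * np.arange(n_lags)
    residue_ids = list(range(2, 2 + n_residues))

    acf_store: dict[int, dict[int, CorrelationFunction]] = {}
    for s in range(n_sims):
        tau_slow = 1.25e-9 * 2.0**s  # 1.25, 2.5, 5, 10, 20 ns across sims
        tau_fast = 20e-12 * 2.0**s  # 20, 40, 80, 160, 320 ps
        per_res = {}
        for j, rid in enumerate(residue_ids):
            w_slow = 0.5 + 0.4 * j / max(1, n_residues - 1)
            per_res[rid] = make_acf(
                weights=[1.0 - w_slow, w_slow],
                taus_s=[tau_fast, tau_slow],
                time_grid_ps=t,
                residue_id=rid,
            )
        acf_store[s] = per_res

    truth_profile, _ = predict_profile(
        list(acf_store[truth_index].values()), params, grid
    )
    if noise_sigma > 0:
        rng = _rng(seed, "selection")
        noisy = {}
        for name in ("t1", "t2", "hetnoe"):
            vals = truth_profile.observable(name)
            noisy[name] = vals * (1.0 + rng.normal(0.0, noise_sigma, vals.shape))
        exp = RelaxationProfile(
            residue_ids=truth_profile.residue_ids,
            t1=noisy["t1"],
            t2=noisy["t2"],
            hetnoe=noisy["hetnoe"],
            field_mhz=field_mhz,
        )
    else:
        exp = truth_profile
    return acf_store, exp, params


def fjc_mean_square_rg(n_beads: int, bond_length: float) -> float:
    """⟨R_g²⟩ of a freely jointed chain of n beads: b²(n² − 1)/(6n)."""
    if n_beads < 1:
        raise ValueError("need at least one bead")
    return bond_length**2 * (n_beads**2 - 1) / (6.0 * n_beads)


def _rigid_domain(size: int, bond: float) -> np.ndarray:
    """A compact frozen bead cluster: beads on a small cubic lattice."""
    side = int(np.ceil(size ** (1.0 / 3.0)))
    pts = []
    for i in range(size):
        pts.append(((i % side), (i // side) % side, i // (side * side)))
    x = np.asarray(pts, dtype=float) * bond
    return x - x.mean(axis=0)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_bead_ensemble(
    n_frames: int,
    domain_sizes: tuple[int, int] = (20, 20),
    linker_length: int = 10,
    bond_length: float = 0.38,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Two rigid bead domains joined by a freely jointed linker.

    Each frame independently redraws the linker conformation (a random
    walk of ``linker_length`` bonds of ``bond_length`` nm, Cα-like default
    0.38 nm) and the global orientations of the two internally frozen
    domains.  One bead per residue, unit masses.  With ``domain_sizes ==
    (1, 1)`` the molecule reduces to a freely jointed chain of
    ``linker_length + 1`` beads whose ⟨R_g²⟩ has the closed form
    :func:`fjc_mean_square_rg`.

    Returns ``(coords (n_frames, n_beads, 3) nm, masses, residue_groups)``.
    """
    if min(domain_sizes) < 1 or linker_length < 0 or n_frames < 1:
        raise ValueError("sizes and frame count must be positive")
    rng = _rng(seed, "beads")
    d1 = _rigid_domain(domain_sizes[0], bond_length)
    d2 = _rigid_domain(domain_sizes[1], bond_length)
    n_link_free = max(0, linker_length - 1)
    n_beads = domain_sizes[0] + n_link_free + domain_sizes[1]

    coords = np.empty((n_frames, n_beads, 3))
    for f in range(n_frames):
        r1 = d1 @ _random_rotation(rng).T
        anchor1 = r1[-1]
        steps = rng.normal(size=(max(linker_length, 1), 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        steps *= bond_length
        walk = anchor1 + np.cumsum(steps, axis=0)
        link_beads = walk[:-1] if linker_length > 0 else np.empty((0, 3))
        anchor2 = walk[-1] if linker_length > 0 else anchor1
        r2 = d2 @ _random_rotation(rng).T
        r2 = r2 - r2[0] + anchor2
        frame = np.concatenate([r1, link_beads[:n_link_free], r2], axis=0)
        coords[f] = frame - frame.mean(axis=0)
    masses = np.ones(n_beads)
    groups = [np.array([i]) for i in range(n_beads)]
    return coords, masses, groups
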