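"""Conformational characterization of selected ensembles.

Operates on bare coordinate arrays in nm (``(n_frames, n_atoms, 3)``) so
the same functions serve MD trajectories (via :mod:`qebss.traj_io`
extractors) and synthetic bead ensembles.  Provided analyses: per-frame
radius of gyration and its histogram, the backbone orientational
correlation map ⟨v_i·v_j⟩ over consecutive-Cα vectors, average
minimum-distance maps between residues, and PCA of Cα positional
fluctuations with per-trajectory projections onto PC1/PC2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EnsembleCharacterization",
    "radius_of_gyration",
    "rg_histogram",
    "orientation_correlation_map",
    "min_distance_map",
    "pca_ensemble",
    "subsample_frames",
]


@dataclass
class EnsembleCharacterization:
    """Bundle of the per-ensemble characterization outputs."""

    rg_values: np.ndarray
    rg_histogram: tuple[np.ndarray, np.ndarray]
    orientation_map: np.ndarray | None = None
    mindist_map: np.ndarray | None = None
    pca: tuple[np.ndarray, np.ndarray, list[np.ndarray]] | None = None


def radius_of_gyration(frames: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted radius of gyration per frame, in nm.

    R_g = sqrt( Σ m_i ‖r_i − r_com‖² / Σ m_i ).
    """
    frames = np.asarray(frames, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    if masses.shape != (frames.shape[1],):
        raise ValueError("masses must match the atom count")
    if np.any(masses < 0) or masses.sum() <= 0:
        raise ValueError("masses must be non-negative with positive total")
    total = masses.sum()
    com = (frames * masses[None, :, None]).sum(axis=1) / total
    d2 = ((frames - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((d2 * masses[None, :]).sum(axis=1) / total)


def rg_histogram(
    rg_values: np.ndarray, bins: int | str = "fd"
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of R_g; Freedman–Diaconis binning by default.

    Returns (bin centers, densities).
    """
    densities, edges = np.histogram(np.asarray(rg_values), bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, densities


def orientation_correlation_map(ca_series: np.ndarray) -> np.ndarray:
    """Time-averaged ⟨v_i·v_j⟩ map over consecutive-Cα unit vectors.

    v_i is the normalized vector from Cα_i to Cα_{i+1}, so an N-residue
    chain yields an (N−1)×(N−1) symmetric matrix with unit diagonal; +1
    means persistently parallel segments, −1 antiparallel, 0 uncorrelated.
    """
    ca = np.asarray(ca_series, dtype=float)
    if ca.ndim != 3 or ca.shape[2] != 3:
        raise ValueError("ca_series must be (n_frames, n_ca, 3)")
    if ca.shape[1] < 3:
        raise ValueError("need at least three CA atoms")
    v = ca[:, 1:, :] - ca[:, :-1, :]
    norms = np.linalg.norm(v, axis=2)
    if np.any(norms <= 1e-12):
        frame, idx = np.argwhere(norms <= 1e-12)[0]
        raise ValueError(
            f"coincident consecutive CA atoms at frame {frame}, segment {idx}"
        )
    v /= norms[:, :, None]
    # average of the per-frame Gram matrices
    m = np.einsum("fia,fja->ij", v, v) / v.shape[0]
    np.fill_diagonal(m, 1.0)
    return m


def min_distance_map(
    frames: np.ndarray,
    residue_groups: Sequence[np.ndarray],
    frame_spacing: float,
    interval: float = 1000.0,
) -> np.ndarray:
    """Average minimum inter-residue distance map (all atoms), in nm.

    Frames are sampled every ``interval`` ps (default 1 ns; must be at
    least the frame spacing); for each residue pair the minimum over all
    atom pairs is taken per sampled frame, then time-averaged.
    """
    frames = np.asarray(frames, dtype=float)
    if interval < frame_spacing:
        raise ValueError("interval must be at least the frame spacing")
    stride = max(1, int(round(interval / frame_spacing)))
    sampled = frames[::stride]
    n_res = len(residue_groups)
    acc = np.zeros((n_res, n_res))
    for frame in sampled:
        for i in range(n_res):
            xi = frame[residue_groups[i]]
            for j in range(i + 1, n_res):
                d = cdist(xi, frame[residue_groups[j]]).min()
                acc[i, j] += d
                acc[j, i] += d
    return acc / len(sampled)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation superposing centered ``mobile`` onto ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    return u @ diag @ vt


def pca_ensemble(
    trajectories: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """PCA of Cα positional fluctuations across concatenated trajectories.

    All frames are centered and least-squares superposed onto the mean
    structure of the concatenated ensemble (one fit iteration), the 3N×3N
    covariance matrix of Cα coordinates is diagonalized, and each input
    trajectory is projected onto the first two eigenvectors.

    Returns (eigenvalues descending, eigenvectors as columns, projections
    per trajectory with shape (n_frames, 2)).
    """
    trajs = [np.asarray(t, dtype=float) for t in trajectories]
    if not trajs:
        raise ValueError("no trajectories given")
    n_ca = trajs[0].shape[1]
    for t in trajs:
        if t.ndim != 3 or t.shape[1] != n_ca or t.shape[2] != 3:
            raise ValueError("inconsistent CA counts across trajectories")
    frames = np.concatenate(trajs, axis=0)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames in total")

    centered = frames - frames.mean(axis=1, keepdims=True)
    mean_struct = centered.mean(axis=0)
    mean_struct -= mean_struct.mean(axis=0)
    fitted = np.empty_like(centered)
    for k, fr in enumerate(centered):
        fitted[k] = fr @ _kabsch(fr, mean_struct)

    flat = fitted.reshape(fitted.shape[0], -1)
    mean_flat = flat.mean(axis=0)
    dev = flat - mean_flat
    cov = dev.T @ dev / dev.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    projections = []
    start = 0
    for t in trajs:
        stop = start + t.shape[0]
        projections.append(dev[start:stop] @ evecs[:, :2])
        start = stop
    return evals, evecs, projections


def subsample_frames(n_frames: int, k: int) -> np.ndarray:
    """Indices of k equally spaced frames (for external snapshot renderers)."""
    if k < 1 or n_frames < 1:
        raise ValueError("need k >= 1 and n_frames >= 1")
    k = min(k, n_frames)
    return np.unique(np.linspace(0, n_frames - 1, k).round().astype(int))
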