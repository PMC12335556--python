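"""Trajectory, vector-series and table I/O.

This module is the boundary between on-disk formats and the in-memory types
used by the physics code.  Trajectory parsing is delegated to MDAnalysis
behind a thin adapter (:class:`TrajectoryHandle`), imported lazily so that
workflows starting from precomputed correlation functions never touch a
trajectory reader.

Unit conventions at the I/O boundary: times in picoseconds, distances in
nanometres.  Relaxation observables (T1, T2) are stored in seconds.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyTrajectoryError,
    FormatError,
    MissingAmideHydrogenError,
)

__all__ = [
    "TrajectoryHandle",
    "VectorSeries",
    "RelaxationProfile",
    "load_trajectory",
    "extract_nh_vectors",
    "extract_ca_coordinates",
    "extract_atom_coordinates",
    "read_relaxation_table",
    "write_relaxation_table",
    "read_xvg_acf",
    "write_xvg",
]

# MDAnalysis positions are in Angstrom; pipeline distances are in nm.
_ANGSTROM_TO_NM = 0.1

# Residue names without a backbone amide hydrogen.
_NO_AMIDE_H = {"PRO", "HYP"}

# Accepted names for the backbone amide hydrogen across force-field dialects.
_AMIDE_H_NAMES = ("H", "HN")


@dataclass(frozen=True)
class VectorSeries:
    """Time series of unit bond vectors for one residue.

    Attributes
    ----------
    residue_id : int
        Author residue number.
    times : ndarray
        Frame times in ps, equally spaced.
    vectors : ndarray, shape (n_frames, 3)
        Unit vectors (|v| = 1 within 1e-6).
    """

    residue_id: int
    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] != t.shape[0]:
            raise ValueError("vectors must be (n_frames, 3) matching times")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(
                f"vectors of residue {self.residue_id} are not unit length"
            )
        if t.size > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be equally spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vectors", v)

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def dt(self) -> float:
        """Frame spacing in ps."""
        if self.times.size < 2:
            raise ValueError("need at least two frames for a spacing")
        return float(self.times[1] - self.times[0])


@dataclass
class RelaxationProfile:
    """Per-residue T1/T2/hetNOE values, predicted or experimental.

    T1 and T2 are in seconds, hetNOE dimensionless; NaN marks a missing
    value.  Optional per-residue errors follow the same convention.
    """

    residue_ids: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    hetnoe: np.ndarray
    t1_err: np.ndarray | None = None
    t2_err: np.ndarray | None = None
    noe_err: np.ndarray | None = None
    field_mhz: float | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        n = self.residue_ids.size
        for name in ("t1", "t2", "hetnoe", "t1_err", "t2_err", "noe_err"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if np.unique(self.residue_ids).size != n:
            raise ValueError("duplicate residue IDs in profile")
        for name in ("t1", "t2"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise ValueError(f"{name} must be positive where present")

    def observable(self, name: str) -> np.ndarray:
        key = {"t1": "t1", "t2": "t2", "hetnoe": "hetnoe", "noe": "hetnoe"}[
            name.lower()
        ]
        return getattr(self, key)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"residue": self.residue_ids, "T1": self.t1, "T2": self.t2,
                "hetNOE": self.hetnoe}
        if self.t1_err is not None:
            cols["T1_err"] = self.t1_err
        if self.t2_err is not None:
            cols["T2_err"] = self.t2_err
        if self.noe_err is not None:
            cols["NOE_err"] = self.noe_err
        return pd.DataFrame(cols)


@dataclass
class TrajectoryHandle:
    """A loaded trajectory after equilibration skipping.

    Wraps an MDAnalysis Universe plus the retained frame indices; the
    physics code only sees coordinate/vector arrays extracted from it.
    """

    frame_count: int
    frame_spacing: float  # ps
    residues: list[tuple[int, str, str]]  # (resid, resname, segid)
    source_paths: tuple[str, ...]
    _universe: object = field(repr=False, default=None)
    _frame_indices: np.ndarray = field(repr=False, default=None)
    _times: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise EmptyTrajectoryError("trajectory has no frames")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def times(self) -> np.ndarray:
        """Retained frame times in ps."""
        return self._times


def load_trajectory(
    topology_path: str | Path,
    trajectory_paths: Sequence[str | Path] | None = None,
    skip_time: float = 0.0,
    frame_spacing: float | None = None,
) -> TrajectoryHandle:
    """Load a trajectory, excluding an initial equilibration period.

    Parameters
    ----------
    topology_path : path
        PDB or GRO topology (a multi-model PDB can serve as both).
    trajectory_paths : paths, optional
        XTC/TRR/DCD/PDB trajectory files read in sequence.
    skip_time : float
        Equilibration time in ps; frames with t < skip_time are dropped.
        Whether to skip (e.g. the first 300 ns when the radius of gyration
        shows clear early conformational changes) is the user's call.
    frame_spacing : float, optional
        Override the frame spacing in ps when the format stores no
        timestamps (multi-model PDB); frame times become index * spacing.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "MDAnalysis is required for trajectory reading; install the "
            "'MDAnalysis' package or start from precomputed ACFs"
        ) from exc

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology not found: {topology_path}")
    paths = [Path(p) for p in (trajectory_paths or [])]
    for p in paths:
        if not p.exists():
            raise FormatError(f"trajectory not found: {p}")

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if paths:
                u = mda.Universe(str(topology_path), *[str(p) for p in paths])
            else:
                u = mda.Universe(str(topology_path))
    except Exception as exc:
        raise FormatError(f"could not read trajectory: {exc}") from exc

    n_total = len(u.trajectory)
    if frame_spacing is not None:
        if frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")
        dt = float(frame_spacing)
        times = dt * np.arange(n_total)
    else:
        times = np.array([ts.time for ts in u.trajectory], dtype=float)
        if n_total > 1:
            dts = np.diff(times)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
                raise FormatError("frame timestamps are not equally spaced")
            dt = float(dts[0])
        else:
            dt = 1.0

    keep = np.nonzero(times >= skip_time)[0]
    if keep.size == 0:
        raise EmptyTrajectoryError(
            f"skip_time={skip_time} ps leaves no frames "
            f"(trajectory spans {times[0]}..{times[-1]} ps)"
        )

    residues = [
        (int(r.resid), str(r.resname), str(getattr(r, "segid", "")))
        for r in u.residues
    ]
    return TrajectoryHandle(
        frame_count=int(keep.size),
        frame_spacing=dt,
        residues=residues,
        source_paths=tuple(
            str(p) for p in [topology_path, *paths]
        ),
        _universe=u,
        _frame_indices=keep,
        _times=times[keep],
    )


def _default_nh_residues(u) -> list:
    """All residues except prolines and the first residue of each segment."""
    out = []
    for seg in u.segments:
        for i, res in enumerate(seg.residues):
            if i == 0:
                continue  # N-terminal amine, no single amide H
            if res.resname.upper() in _NO_AMIDE_H:
                continue
            out.append(res)
    return out


def extract_nh_vectors(
    traj: TrajectoryHandle,
    residue_ids: Sequence[int] | None = None,
) -> list[VectorSeries]:
    """Extract normalized backbone N–H bond vector series per residue.

    By default prolines and the N-terminal residue of each chain are
    excluded: they carry no backbone amide ¹⁵N–H vector.  Passing explicit
    ``residue_ids`` that include such a residue raises
    :class:`MissingAmideHydrogenError`.
    """
    u = traj._universe
    if residue_ids is None:
        residues = _default_nh_residues(u)
    else:
        wanted = set(int(r) for r in residue_ids)
        residues = [r for r in u.residues if int(r.resid) in wanted]
        missing = wanted - {int(r.resid) for r in residues}
        if missing:
            raise MissingAmideHydrogenError(
                f"residues not in topology: {sorted(missing)}"
            )

    n_atoms, h_atoms, ids = [], [], []
    for res in residues:
        names = {a.name: a for a in res.atoms}
        n_at = names.get("N")
        h_at = next((names[k] for k in _AMIDE_H_NAMES if k in names), None)
        if n_at is None or h_at is None:
            if residue_ids is None:
                continue
            raise MissingAmideHydrogenError(
                f"residue {res.resid} ({res.resname}) lacks a backbone "
                "amide N-H pair"
            )
        n_atoms.append(n_at.index)
        h_atoms.append(h_at.index)
        ids.append(int(res.resid))

    n_group = u.atoms[n_atoms]
    h_group = u.atoms[h_atoms]
    nv = np.empty((traj.frame_count, len(ids), 3))
    for k, fi in enumerate(traj._frame_indices):
        u.trajectory[fi]
        nv[k] = h_group.positions - n_group.positions
    nv /= np.linalg.norm(nv, axis=2, keepdims=True)

    return [
        VectorSeries(residue_id=rid, times=traj.times, vectors=nv[:, j])
        for j, rid in enumerate(ids)
    ]


def extract_ca_coordinates(traj: TrajectoryHandle) -> np.ndarray:
    """Cα coordinates in nm, shape (n_frames, n_ca, 3)."""
    u = traj._universe
    ca = u.select_atoms("name CA")
    if len(ca) == 0:
        raise FormatError("topology contains no CA atoms")
    out = np.empty((traj.frame_count, len(ca), 3))
    for k, fi in enumerate(traj._frame_indices):
        u.trajectory[fi]
        out[k] = ca.positions * _ANGSTROM_TO_NM
    return out


def extract_atom_coordinates(
    traj: TrajectoryHandle,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """All-atom coordinates in nm plus masses and per-residue atom indices.

    Returns ``(coords (n_frames, n_atoms, 3), masses, residue_groups)``
    where ``residue_groups[i]`` are the atom indices of residue i.
    """
    u = traj._universe
    coords = np.empty((traj.frame_count, len(u.atoms), 3))
    for k, fi in enumerate(traj._frame_indices):
        u.trajectory[fi]
        coords[k] = u.atoms.positions * _ANGSTROM_TO_NM
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
    except Exception:
        masses = np.ones(len(u.atoms))
    groups = [np.asarray(r.atoms.indices, dtype=int) for r in u.residues]
    return coords, masses, groups


# ---------------------------------------------------------------------------
# Relaxation tables
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "ns": 1e-9}

_COLUMN_ALIASES = {
    "residue": "residue", "res": "residue", "resid": "residue",
    "t1": "T1", "t2": "T2",
    "noe": "hetNOE", "hetnoe": "hetNOE",
    "t1_err": "T1_err", "t2_err": "T2_err",
    "noe_err": "NOE_err", "hetnoe_err": "NOE_err",
}


def _parse_column_token(token: str) -> tuple[str, float]:
    """Split 'T1[ms]' into canonical name and unit scale to seconds."""
    m = re.fullmatch(r"([A-Za-z0-9_]+)(?:\[([^\]]+)\])?", token.strip())
    if m is None:
        raise FormatError(f"unparseable column header token: {token!r}")
    name, unit = m.group(1), m.group(2)
    canonical = _COLUMN_ALIASES.get(name.lower())
    if canonical is None:
        raise FormatError(f"unknown relaxation-table column: {name!r}")
    scale = 1.0
    if unit is not None:
        if canonical in ("hetNOE", "NOE_err") and unit not in ("", "-"):
            raise FormatError(f"hetNOE is dimensionless, got unit {unit!r}")
        if canonical not in ("hetNOE", "NOE_err", "residue"):
            if unit not in _UNIT_SCALE:
                raise FormatError(f"unparseable time unit: {unit!r}")
            scale = _UNIT_SCALE[unit]
    return canonical, scale


def read_relaxation_table(
    path: str | Path,
    dialect: str = "auto",
    field_mhz: float | None = None,
) -> RelaxationProfile:
    """Read a per-residue relaxation table (whitespace or CSV).

    The header row (optionally after ``#``) names the columns, e.g.
    ``# residue T1[s] T2[s] hetNOE`` or ``res,T1,T2,NOE``.  Units in
    brackets are honoured; ``dialect`` forces them: ``"s"`` (default
    assumption), ``"ms"`` (T1/T2 in milliseconds) or ``"auto"``.
    Empty/NaN cells mark missing observables; duplicate residue IDs are an
    error.
    """
    if dialect not in ("auto", "s", "ms"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    raw = path.read_text()

    header_tokens: list[str] | None = None
    data_lines: list[str] = []
    meta_field: float | None = None
    for line in raw.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@")):
            body = stripped.lstrip("#@ ").strip()
            m = re.match(r"field_mhz[\s:=]+([0-9.eE+-]+)", body)
            if m:
                meta_field = float(m.group(1))
                continue
            if body and header_tokens is None and not data_lines:
                tokens = re.split(r"[,\s]+", body)
                if tokens and tokens[0].lower() in ("residue", "res", "resid"):
                    header_tokens = tokens
            continue
        data_lines.append(stripped)

    if not data_lines:
        raise FormatError(f"no data rows in {path}")

    sep = "," if "," in data_lines[0] else r"\s+"
    first_tokens = re.split(r"[,\s]+", data_lines[0])
    if header_tokens is None:
        if first_tokens[0].lower() in ("residue", "res", "resid"):
            header_tokens = first_tokens
            data_lines = data_lines[1:]
        else:
            raise FormatError(
                f"{path}: no recognizable header row naming the columns"
            )

    names, scales = [], []
    for tok in header_tokens:
        name, scale = _parse_column_token(tok)
        names.append(name)
        scales.append(scale)
    if names[0] != "residue":
        raise FormatError("first column must be the residue number")

    df = pd.read_csv(
        io.StringIO("\n".join(data_lines)), sep=sep, header=None,
        names=names, engine="python",
    )
    if df["residue"].duplicated().any():
        dupes = df["residue"][df["residue"].duplicated()].tolist()
        raise FormatError(f"duplicate residue IDs: {dupes}")

    forced = {"s": 1.0, "ms": 1e-3}.get(dialect)
    for name, scale in zip(names, scales):
        if name in ("T1", "T2", "T1_err", "T2_err"):
            df[name] = df[name] * (forced if forced is not None else scale)

    def col(name):
        return df[name].to_numpy(dtype=float) if name in df else None

    return RelaxationProfile(
        residue_ids=df["residue"].to_numpy(dtype=int),
        t1=col("T1") if "T1" in df else np.full(len(df), np.nan),
        t2=col("T2") if "T2" in df else np.full(len(df), np.nan),
        hetnoe=col("hetNOE") if "hetNOE" in df else np.full(len(df), np.nan),
        t1_err=col("T1_err"),
        t2_err=col("T2_err"),
        noe_err=col("NOE_err"),
        field_mhz=field_mhz if field_mhz is not None else meta_field,
    )


def write_relaxation_table(profile: RelaxationProfile, path: str | Path) -> None:
    """Write a profile in the whitespace `# residue T1[s] ...` format."""
    cols = ["residue", "T1[s]", "T2[s]", "hetNOE"]
    arrays = [profile.residue_ids, profile.t1, profile.t2, profile.hetnoe]
    if profile.t1_err is not None:
        cols += ["T1_err[s]", "T2_err[s]", "NOE_err"]
        arrays += [
            profile.t1_err,
            profile.t2_err if profile.t2_err is not None
            else np.full_like(profile.t1_err, np.nan),
            profile.noe_err if profile.noe_err is not None
            else np.full_like(profile.t1_err, np.nan),
        ]
    lines = []
    if profile.field_mhz is not None:
        lines.append(f"# field_mhz {profile.field_mhz:.6g}")
    lines.append("# " + " ".join(cols))
    for row in zip(*arrays):
        rid, rest = row[0], row[1:]
        lines.append(f"{int(rid):d} " + " ".join(f"{v:.17g}" for v in rest))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# xvg correlation files (gmx rotacf output dialect)
# ---------------------------------------------------------------------------

def read_xvg_acf(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column xvg file; returns (times [ps], values)."""
    times, values = [], []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith(("#", "@")):
            continue
        parts = s.split()
        if len(parts) < 2:
            raise FormatError(f"{path}: malformed data line {s!r}")
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    if not times:
        raise FormatError(f"{path}: no data rows")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: times are not strictly increasing")
    return t, np.asarray(values)


def write_xvg(
    path: str | Path,
    times: np.ndarray,
    values: np.ndarray,
    title: str = "rotational correlation function",
) -> None:
    """Write an xvg-compatible two-column ACF file (times in ps)."""
    lines = [
        f'@    title "{title}"',
        '@    xaxis  label "Time (ps)"',
        '@    yaxis  label "C(t)"',
    ]
    for t, v in zip(np.asarray(times), np.asarray(values)):
        lines.append(f"{t:.17g} {v:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
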