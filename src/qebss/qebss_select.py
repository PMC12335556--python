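"""Quality evaluation and ensemble selection.

Each candidate simulation's back-calculated T1, T2 and hetNOE profile is
scored against experiment by a per-observable RMSD averaged over matched
residues.  Dividing each RMSD by the smallest RMSD for that observable
across all candidates yields dimensionless *comparison numbers* (the best
simulation per observable scores exactly 1.0).  A simulation enters the
selected ensemble only if its comparison numbers for all three observables
are strictly below the threshold (default 1.5, i.e. below 150% of the
best) — a conjunction, so the best simulation for one observable can still
be rejected on another.  The selected trajectories form the final ensemble:
their per-residue correlation functions are averaged and the observables
are re-predicted from the averaged curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptySelectionError
from .spin_relax import (
    CorrelationFunction,
    NMRParams,
    TimescaleGrid,
    TimescaleSpectrum,
    average_acfs,
    predict_profile,
)
from .traj_io import RelaxationProfile

__all__ = [
    "OBSERVABLES",
    "RMSDTable",
    "SelectionResult",
    "EnsembleResult",
    "rmsd_observable",
    "build_rmsd_table",
    "comparison_numbers",
    "select_simulations",
    "combine_ensemble",
]

logger = logging.getLogger(__name__)

OBSERVABLES = ("t1", "t2", "hetnoe")


@dataclass
class RMSDTable:
    """Per-simulation, per-observable RMSD versus experiment.

    ``rmsd`` has one row per simulation ID and columns ``rmsd_t1``,
    ``rmsd_t2``, ``rmsd_noe`` (native units: s, s, dimensionless);
    ``n_used`` the matched-residue counts behind each cell.
    """

    rmsd: pd.DataFrame
    n_used: pd.DataFrame

    def __post_init__(self) -> None:
        finite = self.rmsd.to_numpy()[np.isfinite(self.rmsd.to_numpy())]
        if np.any(finite < 0):
            raise ValueError("RMSDs must be non-negative")


@dataclass
class SelectionResult:
    """Comparison numbers plus the outcome of thresholding them."""

    ratios: pd.DataFrame
    threshold: float = 1.5
    selected_ids: list = field(default_factory=list)
    best_per_observable: dict = field(default_factory=dict)


@dataclass
class EnsembleResult:
    """The combined ensemble: averaged ACFs and re-predicted observables."""

    selected_ids: list
    acfs: dict[int, CorrelationFunction]
    profile: RelaxationProfile
    spectra: dict[int, TimescaleSpectrum]
    rmsd: dict[str, float] | None = None


def rmsd_observable(
    sim: RelaxationProfile, exp: RelaxationProfile, observable: str
) -> tuple[float, int]:
    """Root-mean-square deviation over residues matched by ID.

    Only residues present and finite in both profiles contribute;
    experimental errors are not used as weights.  RMSD is in the
    observable's native unit (seconds for T1/T2, dimensionless hetNOE).
    """
    sim_vals = dict(zip(sim.residue_ids, sim.observable(observable)))
    diffs = []
    for rid, exp_val in zip(exp.residue_ids, exp.observable(observable)):
        sim_val = sim_vals.get(int(rid), np.nan)
        if np.isfinite(exp_val) and np.isfinite(sim_val):
            diffs.append(sim_val - exp_val)
    if not diffs:
        raise ValueError(
            f"no residues matched between profiles for observable "
            f"{observable!r}"
        )
    n_dropped = len(sim.residue_ids) - len(diffs)
    if n_dropped:
        logger.info(
            "rmsd_observable(%s): %d simulation residues had no "
            "experimental match and were dropped", observable, n_dropped,
        )
    diffs = np.asarray(diffs)
    return float(np.sqrt(np.mean(diffs**2))), int(diffs.size)


def build_rmsd_table(
    profiles: Mapping[Hashable, RelaxationProfile], exp: RelaxationProfile
) -> RMSDTable:
    """Score every simulation profile against the experimental table."""
    cols = {"t1": "rmsd_t1", "t2": "rmsd_t2", "hetnoe": "rmsd_noe"}
    rows, counts = {}, {}
    for sim_id, profile in profiles.items():
        r, c = {}, {}
        for obs, col in cols.items():
            r[col], c[col] = rmsd_observable(profile, exp, obs)
        rows[sim_id] = r
        counts[sim_id] = c
    return RMSDTable(
        rmsd=pd.DataFrame.from_dict(rows, orient="index"),
        n_used=pd.DataFrame.from_dict(counts, orient="index"),
    )


def comparison_numbers(table: RMSDTable) -> SelectionResult:
    """RMSD of each simulation divided by the per-observable minimum.

    The best simulation per observable scores exactly 1.0.  If the minimum
    RMSD is exactly zero (a noiseless planted truth), the zero-RMSD
    simulation scores 1.0 and every other simulation +inf.
    """
    ratios = {}
    best = {}
    for col in table.rmsd.columns:
        vals = table.rmsd[col]
        if not np.isfinite(vals).any():
            raise ValueError(f"all RMSDs are NaN for {col}")
        m = float(np.nanmin(vals))
        if m == 0.0:
            ratios[col] = pd.Series(
                np.where(vals == 0.0, 1.0, np.inf), index=vals.index
            )
        else:
            ratios[col] = vals / m
        best[col] = vals.idxmin()
    return SelectionResult(ratios=pd.DataFrame(ratios), best_per_observable=best)


def select_simulations(result: SelectionResult, threshold: float = 1.5) -> list:
    """IDs whose comparison numbers are all strictly below the threshold.

    Ties at exactly the threshold are rejected.  The list may be empty; a
    higher threshold never removes a previously selected simulation.
    """
    if threshold <= 1.0:
        raise ValueError(
            "threshold must exceed 1.0: the per-observable best scores "
            "exactly 1.0"
        )
    mask = (result.ratios < threshold).all(axis=1)
    selected = list(result.ratios.index[mask])
    result.threshold = threshold
    result.selected_ids = selected
    return selected


def combine_ensemble(
    selected_ids: Sequence,
    acf_store: Mapping[Hashable, Mapping[int, CorrelationFunction]],
    params: NMRParams,
    grid: TimescaleGrid | None = None,
    exp: RelaxationProfile | None = None,
) -> EnsembleResult:
    """Build the combined ensemble from the selected trajectories.

    Per residue, the correlation functions of the selected simulations are
    averaged first, then fitted and propagated to observables, so the
    ensemble's relaxation times come from the averaged dynamics rather
    than from averaging per-simulation observables.  If ``exp`` is given
    the ensemble RMSDs are recomputed against it.
    """
    if not selected_ids:
        raise EmptySelectionError(
            "no simulations selected; consider reviewing the threshold"
        )
    common = set(acf_store[selected_ids[0]])
    for sid in selected_ids[1:]:
        common &= set(acf_store[sid])
    if not common:
        raise ValueError("selected simulations share no residues")
    avg = {
        rid: average_acfs([acf_store[sid][rid] for sid in selected_ids])
        for rid in sorted(common)
    }
    profile, spectra = predict_profile(list(avg.values()), params, grid)
    rmsd = None
    if exp is not None:
        rmsd = {
            obs: rmsd_observable(profile, exp, obs)[0] for obs in OBSERVABLES
        }
    return EnsembleResult(
        selected_ids=list(selected_ids),
        acfs=avg,
        profile=profile,
        spectra=spectra,
        rmsd=rmsd,
    )
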