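"""Orchestration of the selection protocol.

The protocol has five steps: (1) choose diverse starting structures and
(2) run MD — both external to this package; (3) back-calculate T1/T2/hetNOE
from each trajectory's N–H correlation functions; (4) rank the candidates
against the experimental table and select those whose comparison numbers
for all three observables fall below the threshold; (5) characterize the
combined ensemble.  :func:`run_pipeline` executes steps 3–5 from a store
of per-simulation, per-residue correlation functions and writes a
machine-readable report.

Stage outputs are pure functions of (config, inputs); fitted per-simulation
profiles are cached on disk keyed by a content hash of the ACFs, grid and
parameters, and reused only on hash match.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigError
from .qebss_select import (
    build_rmsd_table,
    combine_ensemble,
    comparison_numbers,
    select_simulations,
)
from .spin_relax import (
    CorrelationFunction,
    NMRParams,
    build_timescale_grid,
    effective_tau,
    predict_profile,
)
from .traj_io import (
    RelaxationProfile,
    read_relaxation_table,
    read_xvg_acf,
    write_relaxation_table,
)

__all__ = ["QEBSSConfig", "run_pipeline", "load_acf_store"]

logger = logging.getLogger(__name__)


@dataclass
class QEBSSConfig:
    """Configuration for one protein's selection run.

    ``ions`` and ``temperature`` are provenance metadata only (they
    document the matched experimental buffer); they affect nothing.
    """

    experimental_table: str
    field_mhz: float
    skip_time_ps: float = 0.0
    residue_mask: list[int] | None = None
    grid_n: int = 100
    grid_tau_min_s: float = 1e-12
    grid_tau_max_s: float = 1e-7
    threshold: float = 1.5
    output_root: str = "qebss_out"
    seed: int = 0
    nmr_overrides: dict = field(default_factory=dict)
    ions: str | None = None
    temperature_k: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QEBSSConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.experimental_table).exists():
            raise ConfigError(
                f"experimental table not found: {self.experimental_table}"
            )
        if self.field_mhz <= 0:
            raise ConfigError("field_mhz must be positive")
        if self.threshold <= 1.0:
            raise ConfigError("threshold must exceed 1.0")
        exp = read_relaxation_table(self.experimental_table)
        if exp.field_mhz is not None and not np.isclose(
            exp.field_mhz, self.field_mhz, rtol=1e-6
        ):
            raise ConfigError(
                f"config field_mhz={self.field_mhz} disagrees with the "
                f"experimental table's declared {exp.field_mhz}"
            )

    def nmr_params(self) -> NMRParams:
        return NMRParams(field_mhz=self.field_mhz, **self.nmr_overrides)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_acf_store(
    acf_dir: str | Path,
) -> dict[str, dict[int, CorrelationFunction]]:
    """Load ``<acf_dir>/<sim_id>/<residue_id>.xvg`` into an ACF store."""
    root = Path(acf_dir)
    store: dict[str, dict[int, CorrelationFunction]] = {}
    for sim_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        per_res = {}
        for f in sorted(sim_dir.glob("*.xvg")):
            rid = int(f.stem)
            lags, values = read_xvg_acf(f)
            per_res[rid] = CorrelationFunction(
                residue_id=rid, lags=lags, values=values
            )
        if per_res:
            store[sim_dir.name] = per_res
    if not store:
        raise ConfigError(f"no ACFs found under {root}")
    return store


def _acf_content_key(
    acfs: Mapping[int, CorrelationFunction], config_hash: str
) -> str:
    h = hashlib.sha256(config_hash.encode())
    for rid in sorted(acfs):
        a = acfs[rid]
        h.update(str(rid).encode())
        h.update(a.lags.tobytes())
        h.update(a.values.tobytes())
    return h.hexdigest()[:24]


def _profile_to_jsonable(profile: RelaxationProfile) -> dict:
    return {
        "residue_ids": profile.residue_ids.tolist(),
        "t1": profile.t1.tolist(),
        "t2": profile.t2.tolist(),
        "hetnoe": profile.hetnoe.tolist(),
        "field_mhz": profile.field_mhz,
    }


def run_pipeline(
    config: QEBSSConfig,
    acf_store: Mapping[Hashable, Mapping[int, CorrelationFunction]],
    write_outputs: bool = True,
) -> dict:
    """Steps 3–5: predict, rank, select, combine; returns the report dict.

    The report body is a pure function of (config, inputs); the wall-clock
    timestamp is added only when writing to disk.
    """
    config.validate()
    exp = read_relaxation_table(config.experimental_table)
    params = config.nmr_params()
    grid = build_timescale_grid(
        config.grid_n, config.grid_tau_min_s, config.grid_tau_max_s
    )
    out_root = Path(config.output_root)
    cache_dir = out_root / "cache"
    cfg_hash = config.content_hash()

    profiles: dict[Hashable, RelaxationProfile] = {}
    spectra_store = {}
    for sim_id, acfs in acf_store.items():
        if config.residue_mask is not None:
            acfs = {r: a for r, a in acfs.items() if r in config.residue_mask}
            if not acfs:
                raise ConfigError(
                    f"residue mask removed every residue of simulation {sim_id}"
                )
        key = _acf_content_key(acfs, cfg_hash)
        cache_file = cache_dir / f"{key}.json"
        if write_outputs and cache_file.exists():
            cached = json.loads(cache_file.read_text())
            profiles[sim_id] = RelaxationProfile(
                residue_ids=np.array(cached["residue_ids"]),
                t1=np.array(cached["t1"]),
                t2=np.array(cached["t2"]),
                hetnoe=np.array(cached["hetnoe"]),
                field_mhz=cached["field_mhz"],
            )
            logger.info("stage=predict sim=%s cache=hit", sim_id)
            continue
        profile, spectra = predict_profile(list(acfs.values()), params, grid)
        profiles[sim_id] = profile
        spectra_store[sim_id] = spectra
        logger.info(
            "stage=predict sim=%s residues=%d", sim_id, len(profile.residue_ids)
        )
        if write_outputs:
            cache_dir.mkdir(parents=True, exist_ok=True)
            cache_file.write_text(json.dumps(_profile_to_jsonable(profile)))

    table = build_rmsd_table(profiles, exp)
    result = comparison_numbers(table)
    selected = select_simulations(result, config.threshold)
    logger.info("stage=rank selected=%s", selected)

    ensemble = combine_ensemble(selected, acf_store, params, grid, exp=exp) \
        if selected else None

    report = {
        "schema_version": 1,
        "qebss_version": __version__,
        "config": asdict(config),
        "config_hash": cfg_hash,
        "rmsd": {
            str(k): {c: float(v) for c, v in row.items()}
            for k, row in table.rmsd.to_dict(orient="index").items()
        },
        "comparison_numbers": {
            str(k): {c: float(v) for c, v in row.items()}
            for k, row in result.ratios.to_dict(orient="index").items()
        },
        "best_per_observable": {
            c: str(v) for c, v in result.best_per_observable.items()
        },
        "selected_ids": [str(s) for s in selected],
        "profiles": {
            str(k): _profile_to_jsonable(p) for k, p in profiles.items()
        },
    }
    if ensemble is not None:
        report["ensemble"] = {
            "profile": _profile_to_jsonable(ensemble.profile),
            "rmsd": {k: float(v) for k, v in ensemble.rmsd.items()},
            "effective_tau_s": {
                str(rid): effective_tau(sp)
                for rid, sp in ensemble.spectra.items()
            },
        }

    if write_outputs:
        import datetime

        out_root.mkdir(parents=True, exist_ok=True)
        for sim_id, profile in profiles.items():
            write_relaxation_table(
                profile, out_root / f"profile_{sim_id}.tsv"
            )
        rank = table.rmsd.join(result.ratios, rsuffix="_ratio")
        rank["selected"] = [i in set(selected) for i in rank.index]
        rank.to_csv(out_root / "rank.tsv", sep="\t", index_label="simulation")
        if ensemble is not None:
            write_relaxation_table(
                ensemble.profile, out_root / "ensemble_profile.tsv"
            )
        on_disk = dict(report)
        on_disk["written_at"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        (out_root / "report.json").write_text(json.dumps(on_disk, indent=2))
    return report
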