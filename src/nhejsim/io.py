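"""Plain-text file formats: damage patterns, depositions, outcomes, configs.

Damage patterns use a minimal SDD-inspired tabular layout — a CSV with one
DSB per row plus a JSON sidecar carrying the exposure metadata — so that
patterns are diffable and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .damage_generation import (
    DSB,
    DamagePattern,
    EnergyDeposition,
    ExposureSpec,
    Nucleus,
)
from .nhej_repair import KineticConfig, MotionParams, RepairOutcome

FORMAT_VERSION = 1

PATTERN_COLUMNS = ["dsb_id", "x_nm", "y_nm", "z_nm", "complexity", "track_id"]
DEPOSITION_COLUMNS = ["x_nm", "y_nm", "z_nm", "energy_ev", "track_id"]


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_pattern(pattern: DamagePattern, path) -> None:
    """Write a pattern CSV and its JSON metadata sidecar."""
    rows = [
        {
            "dsb_id": i,
            "x_nm": d.position_nm[0],
            "y_nm": d.position_nm[1],
            "z_nm": d.position_nm[2],
            "complexity": d.complexity,
            "track_id": d.track_id,
        }
        for i, d in enumerate(pattern.dsbs)
    ]
    pd.DataFrame(rows, columns=PATTERN_COLUMNS).to_csv(path, index=False,
                                                       float_format="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "nucleus_diameter_um": pattern.nucleus.diameter_um,
    }
    if pattern.exposure is not None:
        meta.update(
            species=pattern.exposure.species,
            dose_gy=pattern.exposure.dose_gy,
            let_kev_um=pattern.exposure.let_kev_um,
            seed=pattern.exposure.seed,
        )
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_pattern(path) -> DamagePattern:
    """Read a pattern CSV (+ sidecar if present); inverse of write_pattern."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PATTERN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pattern file missing columns: {sorted(missing)}")
    sidecar = _sidecar_path(path)
    exposure = None
    nucleus = Nucleus()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        nucleus = Nucleus(diameter_um=meta.get("nucleus_diameter_um", 5.0))
        if "species" in meta:
            exposure = ExposureSpec(
                species=meta["species"], dose_gy=meta["dose_gy"],
                let_kev_um=meta["let_kev_um"], seed=meta.get("seed", 0),
            )
    dsbs = tuple(
        DSB(position_nm=(row.x_nm, row.y_nm, row.z_nm),
            complexity=int(row.complexity), track_id=int(row.track_id))
        for row in df.itertuples()
    )
    return DamagePattern(nucleus=nucleus, exposure=exposure, dsbs=dsbs)


def read_depositions(path) -> list[EnergyDeposition]:
    """Read an energy-deposition CSV (x_nm, y_nm, z_nm, energy_ev, track_id)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DEPOSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"deposition file missing columns: {sorted(missing)}")
    return [
        EnergyDeposition(position_nm=(r.x_nm, r.y_nm, r.z_nm),
                         energy_ev=float(r.energy_ev), track_id=int(r.track_id))
        for r in df.itertuples()
    ]


def write_depositions(depositions, path) -> None:
    rows = [
        {"x_nm": d.position_nm[0], "y_nm": d.position_nm[1],
         "z_nm": d.position_nm[2], "energy_ev": d.energy_ev,
         "track_id": d.track_id}
        for d in depositions
    ]
    pd.DataFrame(rows, columns=DEPOSITION_COLUMNS).to_csv(path, index=False,
                                                          float_format="%.17g")


def outcome_to_dict(outcome: RepairOutcome, motion: MotionParams | None = None,
                    kinetics: KineticConfig | None = None) -> dict:
    """JSON-serialisable summary of a repair outcome (with config echo)."""
    out = {
        "n_initial_dsbs": outcome.n_initial_dsbs,
        "n_joined": outcome.n_joined,
        "n_misrepaired": outcome.n_misrepaired,
        "residual_dsb_count": outcome.residual_dsb_count,
        "misrepair_fraction_of_joined": outcome.misrepair_fraction_of_joined,
        "residual_fraction_of_total": outcome.residual_fraction_of_total,
        "displacement_percentiles_nm": outcome.displacement_percentiles((50, 95)),
        "duration_s": outcome.duration_s,
        "valid": outcome.valid,
        "joins": [
            {"end_a": j.end_a, "end_b": j.end_b, "time_s": j.time_s,
             "correct": j.correct}
            for j in outcome.joins
        ],
    }
    if motion is not None:
        out["motion"] = dataclasses.asdict(motion)
    if kinetics is not None:
        out["kinetics"] = dataclasses.asdict(kinetics)
    return out


def load_repair_config(path) -> tuple[MotionParams, KineticConfig]:
    """Load motion/kinetics overrides from a YAML (or JSON) config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    motion = MotionParams(**raw.get("motion", {}))
    kinetics = KineticConfig(**raw.get("kinetics", {}))
    return motion, kinetics
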