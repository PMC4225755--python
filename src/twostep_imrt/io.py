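"""JSON/CSV round-tripping of structure sets, plans, shift records, and
beta* tables.

All writers emit canonical JSON (sorted keys, fixed indentation, repr
floats), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import DVH, Plan, Segment
from .finetune import LeafShiftRecord
from .geometry import Contour, StructureSet
from .twostep import BetaStarTable


def _dump(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def _load(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# -- structure sets ---------------------------------------------------------


def structure_set_to_dict(ss: StructureSet) -> dict:
    return {
        "meta": {
            "slice_thickness_mm": ss.slice_thickness,
            "resolution_mm": ss.in_plane_resolution,
            "isocenter_mm": list(ss.isocenter),
        },
        "structures": {
            name: [{"z_mm": c.slice_z, "points_mm": c.points.tolist()}
                   for c in cs]
            for name, cs in ss.structures.items()
        },
    }


def structure_set_from_dict(d: dict) -> StructureSet:
    meta = d["meta"]
    structs = {
        name: [Contour(c["z_mm"], np.asarray(c["points_mm"], dtype=float))
               for c in cs]
        for name, cs in d["structures"].items()
    }
    return StructureSet(structs, meta["slice_thickness_mm"],
                        meta["resolution_mm"], tuple(meta["isocenter_mm"]))


def write_structure_set(ss: StructureSet, path: str | Path) -> None:
    _dump(structure_set_to_dict(ss), path)


def read_structure_set(path: str | Path) -> StructureSet:
    return structure_set_from_dict(_load(path))


# -- plans and shift records ------------------------------------------------


def plan_to_dict(plan: Plan) -> dict:
    return {
        "beams": list(plan.beams),
        "prescriptions": dict(plan.prescriptions),
        "fractions": plan.fractions,
        "segments": [
            {
                "angle_deg": s.gantry_angle,
                "type": s.step_type,
                "target": s.target,
                "side": s.side,
                "mu": s.mu,
                "leaves": {str(k): list(v) for k, v in sorted(s.leaves.items())},
            }
            for s in plan.segments
        ],
    }


def plan_from_dict(d: dict) -> Plan:
    segs = [
        Segment(s["angle_deg"],
                {int(k): tuple(v) for k, v in s["leaves"].items()},
                s["mu"], s["type"], s["target"], s.get("side"))
        for s in d["segments"]
    ]
    return Plan(segs, dict(d["prescriptions"]), d["fractions"], list(d["beams"]))


def write_plan(plan: Plan, path: str | Path,
               record: LeafShiftRecord | None = None) -> None:
    data = plan_to_dict(plan)
    if record is not None:
        data["leaf_shift_record"] = record_to_dict(record)
    _dump(data, path)


def read_plan(path: str | Path) -> tuple[Plan, LeafShiftRecord | None]:
    d = _load(path)
    record = (record_from_dict(d["leaf_shift_record"])
              if "leaf_shift_record" in d else None)
    return plan_from_dict(d), record


def record_to_dict(record: LeafShiftRecord) -> dict:
    return {
        "shifts": [
            {"key": list(key),
             "pairs": {str(k): list(v) for k, v in sorted(per.items())}}
            for key, per in sorted(record.shifts.items(),
                                   key=lambda kv: repr(kv[0]))
        ],
        "target_extents": {t: list(e) for t, e in record.target_extents.items()},
    }


def record_from_dict(d: dict) -> LeafShiftRecord:
    rec = LeafShiftRecord()
    for entry in d["shifts"]:
        key = tuple(entry["key"])
        rec.shifts[key] = {int(k): tuple(v) for k, v in entry["pairs"].items()}
    rec.target_extents = {t: tuple(e) for t, e in d["target_extents"].items()}
    return rec


# -- native plan bundles ----------------------------------------------------


def write_native_plan(native, path: str | Path) -> None:
    """Serialize a planning-geometry bundle (plan, pre-fine-tune plan,
    shift record, calibration, labels); the structure set is stored in its
    own file by the caller."""
    _dump({
        "plan": plan_to_dict(native.plan),
        "plan_pre": plan_to_dict(native.plan_pre),
        "record": record_to_dict(native.record),
        "calibration": native.calibration,
        "targets": list(native.targets),
        "oar": native.oar,
        "mlc": {"leaf_width_mm": native.mlc.leaf_width_mm,
                "field_half_width_mm": native.mlc.field_half_width_mm},
    }, path)


def read_native_plan(path: str | Path, ss: StructureSet):
    from .adaptation import NativePlan
    from .geometry import MLCSpec

    d = _load(path)
    return NativePlan(
        ss, plan_from_dict(d["plan"]), plan_from_dict(d["plan_pre"]),
        record_from_dict(d["record"]), d["calibration"],
        targets=tuple(d["targets"]), oar=d["oar"],
        mlc=MLCSpec(**d["mlc"]))


# -- beta* tables -----------------------------------------------------------


def write_beta_table(table: BetaStarTable, path: str | Path) -> None:
    _dump(table.to_dict(), path)


def read_beta_table(path: str | Path) -> BetaStarTable:
    return BetaStarTable.from_dict(_load(path))


# -- DVH export -------------------------------------------------------------


def dvh_to_csv(dvhs: list[DVH], path: str | Path, n_bins: int = 256) -> None:
    rows = []
    for dvh in dvhs:
        dose, frac, vol = dvh.curve(n_bins)
        for d, f, v in zip(dose, frac, vol):
            rows.append((dvh.structure, d, v, f))
    pd.DataFrame(rows, columns=["structure", "dose_Gy", "volume_cm3",
                                "volume_fraction"]).to_csv(path, index=False)


__all__ = [
    "dvh_to_csv", "plan_from_dict", "plan_to_dict", "read_beta_table",
    "read_plan", "read_structure_set", "record_from_dict", "record_to_dict",
    "structure_set_from_dict", "structure_set_to_dict", "write_beta_table",
    "write_plan", "write_structure_set",
]
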