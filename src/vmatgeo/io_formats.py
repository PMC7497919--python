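"""Structure-set input (DICOM RTSTRUCT and JSON), PTV selection by naming
convention, YAML config and the JSON plan-geometry report.

Coordinates are DICOM patient-based LPS millimetres throughout; contours are
taken verbatim (no resampling, no added margin — clinical PTVs already carry
their setup margin).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "Lesion",
    "StructureSet",
    "PtvNameRule",
    "DEFAULT_PTV_RULE",
    "read_rtstruct",
    "read_lesions_json",
    "write_lesions_json",
    "select_ptvs",
    "load_config",
    "build_report",
    "write_report",
    "read_report",
    "FormatError",
]

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


@dataclass
class Lesion:
    """One PTV: identifier, optional prescription dose, and its 3-D surface
    points (patient frame, mm).  The centroid is the mean of the points."""

    id: str
    name: str
    points: np.ndarray
    prescription_dose_gy: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 4:
            raise FormatError(f"lesion {self.id!r} has <4 points")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class StructureSet:
    lesions: list[Lesion]
    frame_of_reference_id: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        ids = [l.id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate lesion ids in structure set")


@dataclass(frozen=True)
class PtvNameRule:
    """PTV selection by naming convention: a regex with one numeric capture
    group for the prescription dose; captured values above ``cgy_threshold``
    are read as cGy, otherwise Gy."""

    pattern: str = r"(?i)^PTV[\s_\-]*(\d+(?:\.\d+)?)"
    cgy_threshold: float = 100.0

    def __post_init__(self) -> None:
        rx = re.compile(self.pattern)
        if rx.groups < 1:
            raise ValueError("PTV name pattern needs one numeric capture group")
        if self.cgy_threshold <= 0:
            raise ValueError("cGy threshold must be positive")

    def dose_gy(self, name: str) -> float | None:
        m = re.match(self.pattern, name.strip())
        if not m:
            return None
        value = float(m.group(1))
        return value / 100.0 if value > self.cgy_threshold else value


DEFAULT_PTV_RULE = PtvNameRule()


def read_rtstruct(path) -> StructureSet:
    """Read a DICOM RT Structure Set: per ROI, all contour vertices are
    concatenated into the lesion's point set (verbatim mm, patient frame)."""
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not readable as DICOM ({exc})") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(f"{path}: modality {getattr(ds, 'Modality', None)!r}, expected RTSTRUCT")

    roi_names = {}
    frames = set()
    for roi in getattr(ds, "StructureSetROISequence", []):
        roi_names[int(roi.ROINumber)] = str(roi.ROIName)
        for_uid = getattr(roi, "ReferencedFrameOfReferenceUID", None)
        if for_uid:
            frames.add(str(for_uid))
    if len(frames) > 1:
        raise FormatError(f"{path}: mixed frames of reference {sorted(frames)}")

    lesions = []
    seen: dict[str, int] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = roi_names.get(number, f"ROI{number}")
        contours = getattr(rc, "ContourSequence", None)
        if not contours:
            raise FormatError(f"{path}: ROI {name!r} has no contour data")
        pts = []
        for contour in contours:
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            pts.append(data)
        points = np.concatenate(pts, axis=0)
        # duplicate ROI names get deterministic numeric suffixes
        count = seen.get(name, 0)
        seen[name] = count + 1
        lesion_id = name if count == 0 else f"{name}#{count + 1}"
        lesions.append(Lesion(id=lesion_id, name=name, points=points))
    logger.info("read %d ROI(s) from %s", len(lesions), path)
    return StructureSet(
        lesions=lesions,
        frame_of_reference_id=next(iter(frames)) if frames else None,
        source=str(path),
    )


def read_lesions_json(path) -> StructureSet:
    """Read the JSON lesion format (see ``write_lesions_json`` for schema)."""
    with open(path) as f:
        doc = json.load(f)
    if "lesions" not in doc:
        raise FormatError(f"{path}: missing 'lesions' key")
    lesions = [
        Lesion(
            id=str(entry["id"]),
            name=str(entry.get("name", entry["id"])),
            points=np.asarray(entry["points"], dtype=float),
            prescription_dose_gy=entry.get("prescription_dose_gy"),
        )
        for entry in doc["lesions"]
    ]
    logger.info("read %d lesion(s) from %s", len(lesions), path)
    return StructureSet(
        lesions=lesions,
        frame_of_reference_id=doc.get("frame_of_reference_id"),
        source=str(path),
    )


def write_lesions_json(structure_set: StructureSet, path) -> None:
    """Write the JSON lesion format:

    ``{"format_version": 1, "frame_of_reference_id": ..., "lesions":
    [{"id", "name", "prescription_dose_gy", "points": [[x,y,z], ...]}]}``
    """
    doc = {
        "format_version": 1,
        "frame_of_reference_id": structure_set.frame_of_reference_id,
        "lesions": [
            {
                "id": l.id,
                "name": l.name,
                "prescription_dose_gy": l.prescription_dose_gy,
                "points": [[float(v) for v in p] for p in l.points],
            }
            for l in structure_set.lesions
        ],
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)
        f.write("\n")


def select_ptvs(
    structure_set: StructureSet, rule: PtvNameRule = DEFAULT_PTV_RULE
) -> tuple[dict[float, list[Lesion]], list[Lesion]]:
    """Select PTVs whose names match the naming convention and group them by
    prescription dose (Gy).  Returns (dose_gy -> lesions, non-matching
    structures left for manual selection)."""
    groups: dict[float, list[Lesion]] = {}
    unmatched: list[Lesion] = []
    for lesion in structure_set.lesions:
        dose = rule.dose_gy(lesion.name)
        if dose is None:
            unmatched.append(lesion)
            continue
        lesion.prescription_dose_gy = dose
        groups.setdefault(dose, []).append(lesion)
    if not groups:
        logger.warning("no structures matched the PTV naming convention")
    return dict(sorted(groups.items())), unmatched


DEFAULT_CONFIG: dict = {
    "machine": "HD120",
    "criteria": {"x_max_mm": None, "y_max_mm": None},  # None -> machine default
    "check_angles": [0.0, 45.0, 270.0, 315.0],
    "projection": {"mode": "parallel", "sad_mm": 1000.0},
    "dispatcher": {"max_exhaustive_lesions": 7, "max_exhaustive_isocenters": 3},
    "kmeans": {"repeats": None, "seed": 20160701},  # repeats None -> lesion count
    "scan": {"gantry_step_deg": 2.0, "coll_step_deg": 5.0, "coll_range": [0.0, 165.0]},
    "arcs": None,  # None -> default four-arc set
    "jaw_margin_mm": 0.0,
    "ptv_rule": {"pattern": DEFAULT_PTV_RULE.pattern, "cgy_threshold": 100.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, overlaid on the documented defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return _deep_merge(DEFAULT_CONFIG, user)


# --- plan-geometry report ---------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def build_report(clustering, plans, machine, config: dict, seed: int | None) -> dict:
    """Assemble the plan-geometry report: clusters, feasibility extents,
    per-arc collimator scans and jaws, plus config echo for provenance."""
    criteria = machine.default_criteria
    if config.get("criteria", {}).get("x_max_mm") is not None:
        from .isocenter import DistanceCriteria

        criteria = DistanceCriteria(
            config["criteria"]["x_max_mm"], config["criteria"]["y_max_mm"]
        )
    report = {
        "tool": "vmatgeo",
        "version": TOOL_VERSION,
        "seed": seed,
        "machine": machine.name,
        "criteria_mm": {"x_max": criteria.x_max_mm, "y_max": criteria.y_max_mm},
        "clustering": {
            "method": clustering.method,
            "n_isocenters": clustering.n_isocenters,
            "total_ssed_mm2": clustering.total_ssed,
            "n_feasible_candidates": clustering.n_feasible_candidates,
        },
        "clusters": [],
        "config": _jsonify(config),
    }
    plan_by_index = {p.cluster_index: p for p in plans}
    for ci, cluster in enumerate(clustering.clusters):
        entry = {
            "lesion_ids": list(cluster.lesion_ids),
            "isocenter_mm": _jsonify(cluster.isocenter),
            "ssed_mm2": cluster.ssed,
            "feasibility": {
                f"{angle:g}": {
                    "extents_mm": list(ext.as_tuple()),
                    "pass": ok,
                }
                for angle, (ext, ok) in cluster.feasibility.per_angle.items()
            },
            "arcs": [],
        }
        plan = plan_by_index.get(ci)
        if plan is not None:
            for ag in plan.arcs:
                entry["arcs"].append(
                    {
                        "arc_id": ag.arc.id,
                        "couch_deg": ag.arc.couch_deg,
                        "gantry_start_deg": ag.arc.gantry_start_deg,
                        "gantry_stop_deg": ag.arc.gantry_stop_deg,
                        "direction": ag.arc.direction,
                        "collimator_deg": ag.collimator_deg,
                        "jaws_mm": {
                            "x1": ag.jaws.x1_mm,
                            "x2": ag.jaws.x2_mm,
                            "y1": ag.jaws.y1_mm,
                            "y2": ag.jaws.y2_mm,
                        },
                        "scan": {
                            "angles_deg": ag.scan.angles_deg,
                            "total_areas_mm2": ag.scan.total_areas_mm2,
                        },
                    }
                )
        report["clusters"].append(entry)
    return report


def write_report(report: dict, path) -> None:
    """Write the report as JSON: stable key order, full float precision, so
    write→read→write is byte-identical."""
    with open(path, "w") as f:
        json.dump(_jsonify(report), f, indent=1, sort_keys=True)
        f.write("\n")


def read_report(path) -> dict:
    with open(path) as f:
        return json.load(f)
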