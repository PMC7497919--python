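"""End-to-end driver: structure set in, plan-geometry report out.

Glues the stages together the way the CLI and the examples use them:
select PTVs (optionally grouped by prescription dose), cluster each group
into the minimum number of feasible isocenters, then optimize collimator
angle and jaws for every (cluster, arc) pair.
"""

from __future__ import annotations

import logging

from . import clustering as _clustering
from . import collimator as _collimator
from .io_formats import (
    DEFAULT_PTV_RULE,
    PtvNameRule,
    StructureSet,
    build_report,
    select_ptvs,
)
from .isocenter import DistanceCriteria
from .mlc import get_machine

__all__ = ["optimize_case"]

logger = logging.getLogger(__name__)


def _arcs_from_config(arc_cfg):
    if arc_cfg is None:
        return _collimator.default_arcs()
    arcs = []
    for i, a in enumerate(arc_cfg):
        arcs.append(
            _collimator.Arc(
                id=a.get("id", f"arc{i + 1}"),
                couch_deg=float(a["couch"]),
                gantry_start_deg=float(a["start"]),
                gantry_stop_deg=float(a["stop"]),
                direction=a.get("direction", "CW"),
                full=bool(a.get("full", False)),
            )
        )
    return arcs


def optimize_case(
    structure_set: StructureSet,
    config: dict,
    seed: int | None = None,
    select_by_name: bool = False,
) -> dict:
    """Run the full geometry optimization for one case and return the
    plan-geometry report (a JSON-ready dict).

    With ``select_by_name`` the PTV naming rule filters and dose-groups the
    structures and each dose group is optimized independently; otherwise all
    structures are treated as one group of targets.
    """
    machine = get_machine(config["machine"])
    crit_cfg = config.get("criteria", {})
    if crit_cfg.get("x_max_mm") is not None:
        criteria = DistanceCriteria(crit_cfg["x_max_mm"], crit_cfg["y_max_mm"])
    else:
        criteria = machine.default_criteria
    check_angles = tuple(config["check_angles"])
    mode = config["projection"]["mode"]
    disp = config["dispatcher"]
    km = config["kmeans"]
    scan = config["scan"]
    arcs = _arcs_from_config(config.get("arcs"))
    kmeans_seed = km["seed"] if seed is None else seed

    if select_by_name:
        rule_cfg = config.get("ptv_rule", {})
        rule = PtvNameRule(
            pattern=rule_cfg.get("pattern", DEFAULT_PTV_RULE.pattern),
            cgy_threshold=rule_cfg.get("cgy_threshold", 100.0),
        )
        groups, unmatched = select_ptvs(structure_set, rule)
        if unmatched:
            logger.info(
                "%d structure(s) did not match the PTV rule: %s",
                len(unmatched),
                [l.name for l in unmatched],
            )
        group_list = [(dose, lesions) for dose, lesions in groups.items()]
    else:
        group_list = [(None, list(structure_set.lesions))]

    reports = []
    for dose, lesions in group_list:
        result = _clustering.optimize_isocenters(
            lesions,
            criteria,
            max_exhaustive_lesions=disp["max_exhaustive_lesions"],
            max_exhaustive_isocenters=disp["max_exhaustive_isocenters"],
            kmeans_repeats=km["repeats"],
            kmeans_seed=kmeans_seed,
            check_angles=check_angles,
            mode=mode,
        )
        lesions_by_id = {l.id: l for l in lesions}
        plans = _collimator.optimize_plan_geometry(
            result,
            arcs,
            machine,
            lesions_by_id,
            gantry_step_deg=scan["gantry_step_deg"],
            coll_step_deg=scan["coll_step_deg"],
            coll_range=tuple(scan["coll_range"]),
            jaw_margin_mm=config.get("jaw_margin_mm", 0.0),
            mode=mode,
        )
        group_report = build_report(result, plans, machine, config, seed)
        if dose is not None:
            group_report["prescription_dose_gy"] = dose
        reports.append(group_report)

    if len(reports) == 1:
        return reports[0]
    return {
        "tool": "vmatgeo",
        "version": reports[0]["version"],
        "seed": seed,
        "machine": machine.name,
        "dose_groups": reports,
    }
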