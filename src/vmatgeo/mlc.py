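"""MLC machine models, leaf-pair aperture fitting and jaw fitting.

Two Varian MLCs are modeled from vendor geometry (see ``data/machines.json``):

* **HD120** — 32 central 2.5 mm leaf pairs (covering y ∈ [−40, +40] mm) plus
  14 outer 5 mm pairs per side; Y jaws capped at ±40 mm so only the fine
  central leaves are used, with default BEV criteria 50 mm (X) / 40 mm (Y).
* **Millennium 120 (M120)** — 40 central 5 mm pairs plus 10 outer 10 mm
  pairs per side; default criteria 50 mm / 50 mm.

``fit_leaves`` opens, for each leaf pair, a single X interval spanning
everything the projected outer boundary (POB) puts into that pair's band.
Because one pair cannot close between two targets it must span, the gap
between separated lesions counts toward the opening area — the "island
blocking" cost that the collimator-angle optimization minimizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import ProjectedBoundary
from .isocenter import DistanceCriteria

__all__ = [
    "MachineModel",
    "ApertureFit",
    "JawSetting",
    "builtin_machines",
    "get_machine",
    "fit_leaves",
    "opening_area",
    "fit_jaws",
]


@dataclass(frozen=True)
class MachineModel:
    name: str
    mlc_type: str
    leaf_pair_edges_mm: tuple[float, ...]  # 61 strictly increasing Y planes
    max_field_x_mm: float
    max_field_y_mm: float
    sad_mm: float
    default_criteria: DistanceCriteria
    y_jaw_cap_mm: float | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.leaf_pair_edges_mm, float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("leaf edges must be strictly increasing")
        if abs(edges[0] + edges[-1]) > 1e-9:
            raise ValueError("leaf edges must be symmetric about 0")

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_pair_edges_mm) - 1

    @property
    def pair_widths_mm(self) -> np.ndarray:
        return np.diff(np.asarray(self.leaf_pair_edges_mm, float))


@dataclass
class ApertureFit:
    """Open leaf pairs for one gantry/collimator sample: (pair_index,
    x_left, x_right) for open pairs only, plus the summed opening area."""

    pairs: list[tuple[int, float, float]]
    total_area_mm2: float


@dataclass
class JawSetting:
    """Rectangular field edges in the collimator frame (x1 < x2, y1 < y2)."""

    x1_mm: float
    x2_mm: float
    y1_mm: float
    y2_mm: float


def _load_machine_fixture() -> dict:
    text = resources.files("vmatgeo.data").joinpath("machines.json").read_text()
    return json.loads(text)


def builtin_machines() -> dict[str, MachineModel]:
    """The built-in machine models, keyed by name (HD120, M120)."""
    doc = _load_machine_fixture()
    machines = {}
    for m in doc["machines"]:
        crit = m["default_criteria"]
        machines[m["name"]] = MachineModel(
            name=m["name"],
            mlc_type=m["mlc_type"],
            leaf_pair_edges_mm=tuple(m["leaf_pair_edges_mm"]),
            max_field_x_mm=m["max_field_x_mm"],
            max_field_y_mm=m["max_field_y_mm"],
            sad_mm=m["sad_mm"],
            default_criteria=DistanceCriteria(crit["x_max_mm"], crit["y_max_mm"]),
            y_jaw_cap_mm=m["y_jaw_cap_mm"],
        )
    return machines


def get_machine(name: str) -> MachineModel:
    machines = builtin_machines()
    if name not in machines:
        raise KeyError(
            f"unknown machine {name!r}; valid names: {sorted(machines)}"
        )
    return machines[name]


def _bands_x_ranges(poly: np.ndarray, band_lo: np.ndarray, band_hi: np.ndarray):
    """Exact X extrema of a polygon clipped to each band y ∈ [lo_b, hi_b].

    Works edge-wise: each polygon edge contributes, per band, the X values
    where its parameter interval meets the band (vertices inside a band are
    the endpoints of their two incident edges, boundary crossings are the
    clipped interval ends), so the extrema of the analytic clip region are
    recovered without building clip polygons.  A band counts as open only
    when the overlap has positive height — the half-open band convention: a
    polygon merely touching a leaf boundary does not open the band above it.

    Returns (x_min, x_max, open) arrays over bands; closed bands hold ±inf.
    """
    x1 = poly[:, 0]
    y1 = poly[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    dy = y2 - y1
    horiz = dy == 0
    dy_safe = np.where(horiz, 1.0, dy)

    lo = band_lo[:, None]
    hi = band_hi[:, None]
    t_a = (lo - y1) / dy_safe
    t_b = (hi - y1) / dy_safe
    t_min = np.clip(np.minimum(t_a, t_b), 0.0, 1.0)
    t_max = np.clip(np.maximum(t_a, t_b), 0.0, 1.0)
    # edge meets the (closed) band at all?
    overlaps = (np.minimum(y1, y2) <= hi) & (np.maximum(y1, y2) >= lo)
    valid = overlaps & ~horiz
    valid_h = horiz & (y1 >= lo) & (y1 <= hi)

    dx = x2 - x1
    xa = x1 + t_min * dx
    xb = x1 + t_max * dx
    xa = np.where(valid, xa, np.inf)
    xb = np.where(valid, xb, np.inf)
    xh1 = np.where(valid_h, x1, np.inf)
    xh2 = np.where(valid_h, x2, np.inf)
    x_min = np.minimum.reduce(
        [xa.min(axis=1), xb.min(axis=1), xh1.min(axis=1), xh2.min(axis=1)]
    )
    xa = np.where(np.isinf(xa), -np.inf, xa)
    xb = np.where(np.isinf(xb), -np.inf, xb)
    xh1 = np.where(np.isinf(xh1), -np.inf, xh1)
    xh2 = np.where(np.isinf(xh2), -np.inf, xh2)
    x_max = np.maximum.reduce(
        [xa.max(axis=1), xb.max(axis=1), xh1.max(axis=1), xh2.max(axis=1)]
    )
    open_band = (y1.max() > band_lo) & (y1.min() < band_hi) & np.isfinite(x_min)
    return x_min, x_max, open_band


def fit_leaves(pob: ProjectedBoundary, machine: MachineModel) -> ApertureFit:
    """Fit the leaf pairs to a POB already expressed in the MLC frame.

    Every pair whose band intersects the POB opens one interval from the
    smallest to the largest clipped X — gaps between islands stay open.
    """
    edges = np.asarray(machine.leaf_pair_edges_mm, float)
    verts = pob.all_vertices()
    if verts[:, 1].min() < edges[0] - 1e-9 or verts[:, 1].max() > edges[-1] + 1e-9:
        raise ValueError(
            f"POB spans y ∈ [{verts[:, 1].min():.1f}, {verts[:, 1].max():.1f}] mm, "
            f"outside the {machine.name} MLC range [{edges[0]}, {edges[-1]}] mm"
        )
    lo = int(np.searchsorted(edges, verts[:, 1].min(), side="right") - 1)
    hi = int(np.searchsorted(edges, verts[:, 1].max(), side="left"))
    lo = max(lo, 0)
    hi = min(hi, machine.n_pairs)

    band_lo = edges[lo:hi]
    band_hi = edges[lo + 1 : hi + 1]
    x_min = np.full(hi - lo, np.inf)
    x_max = np.full(hi - lo, -np.inf)
    is_open = np.zeros(hi - lo, dtype=bool)
    for poly in pob.polygons:
        pmin, pmax, popen = _bands_x_ranges(poly, band_lo, band_hi)
        x_min = np.where(popen, np.minimum(x_min, pmin), x_min)
        x_max = np.where(popen, np.maximum(x_max, pmax), x_max)
        is_open |= popen
    is_open &= x_min < x_max
    widths = band_hi - band_lo
    areas = np.where(is_open, widths * (x_max - x_min), 0.0)
    pairs = [
        (int(lo + i), float(x_min[i]), float(x_max[i]))
        for i in np.nonzero(is_open)[0]
    ]
    return ApertureFit(pairs=pairs, total_area_mm2=float(areas.sum()))


def opening_area(fit: ApertureFit) -> float:
    """Total MLC opening area (mm²) of an aperture fit."""
    return fit.total_area_mm2


def fit_jaws(
    pobs_over_arc: list[ProjectedBoundary],
    collimator_deg: float,
    machine: MachineModel,
    margin_mm: float = 0.0,
) -> JawSetting:
    """Bounding jaw positions covering every POB sampled along an arc
    (already in the MLC frame), expanded by ``margin_mm`` and Y-clamped to
    the machine's jaw cap when one is set."""
    if not pobs_over_arc:
        raise ValueError("jaw fitting needs at least one POB")
    verts = np.concatenate([p.all_vertices() for p in pobs_over_arc], axis=0)
    x1 = float(verts[:, 0].min()) - margin_mm
    x2 = float(verts[:, 0].max()) + margin_mm
    y1 = float(verts[:, 1].min()) - margin_mm
    y2 = float(verts[:, 1].max()) + margin_mm
    if x2 - x1 > machine.max_field_x_mm:
        raise ValueError(
            f"X field span {x2 - x1:.1f} mm exceeds {machine.name} limit "
            f"{machine.max_field_x_mm} mm"
        )
    if machine.y_jaw_cap_mm is not None:
        cap = machine.y_jaw_cap_mm
        y1 = max(y1, -cap)
        y2 = min(y2, cap)
    return JawSetting(x1_mm=x1, x2_mm=x2, y1_mm=y1, y2_mm=y2)
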