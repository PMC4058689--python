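"""Parametric coronary-tree geometry.

A :class:`CoronaryTree` is a rooted tree of :class:`VesselSegment` objects,
each an axisymmetric vessel parameterized by arclength with a sampled
diameter profile (linear interpolation between samples). The built-in
emulator reproduces the topology of a porcine left anterior descending
(LAD) artery: a tapering main trunk at least 2 mm in diameter carrying
seven primary branches, each at least 1 mm in diameter, with four named
stenosis locations ("A" proximal to "D" distal) on the trunk between
branch take-offs.

Idealized concentric stenoses are inserted by multiplying the normal
diameter profile by ``1 - ds * w(s)`` where the window ``w`` rises from 0
at the extent edges to 1 at the throat, so the throat diameter is exactly
``(1 - ds)`` times the local normal diameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

TREE_SCHEMA_VERSION = "1.0"

DEFAULT_BRANCH_POSITIONS_MM = (10.0, 30.0, 42.0, 54.0, 66.0, 78.0, 90.0)
DEFAULT_BRANCH_DIAMETERS_MM = (2.0, 1.8, 1.6, 1.5, 1.3, 1.2, 1.0)
DEFAULT_LOCATIONS_MM = {"A": 20.0, "B": 36.0, "C": 60.0, "D": 84.0}


class GeometryError(ValueError):
    """Raised for invalid tree geometry or stenosis specifications."""


@dataclass(frozen=True)
class VesselSegment:
    """One vessel segment: arclength s in [0, L] mm with diameter d(s) in mm."""

    id: str
    length: float
    samples_s: tuple[float, ...]
    samples_d: tuple[float, ...]
    role: str = "branch"  # trunk | branch

    def __post_init__(self) -> None:
        s = np.asarray(self.samples_s, dtype=float)
        d = np.asarray(self.samples_d, dtype=float)
        if self.length <= 0:
            raise GeometryError(f"segment {self.id!r}: length must be positive")
        if s.size != d.size or s.size < 2:
            raise GeometryError(f"segment {self.id!r}: need >= 2 (s, d) samples of equal length")
        if np.any(np.diff(s) <= 0):
            raise GeometryError(f"segment {self.id!r}: samples must be strictly increasing in s")
        if not math.isclose(s[0], 0.0, abs_tol=1e-12):
            raise GeometryError(f"segment {self.id!r}: first sample must be at s=0")
        if not math.isclose(s[-1], self.length, rel_tol=1e-12, abs_tol=1e-12):
            raise GeometryError(f"segment {self.id!r}: last sample must be at s=length")
        if np.any(d <= 0):
            raise GeometryError(f"segment {self.id!r}: all sampled diameters must be positive")
        if self.role not in ("trunk", "branch"):
            raise GeometryError(f"segment {self.id!r}: role must be trunk or branch")

    def diameter(self, s: float | np.ndarray) -> np.ndarray | float:
        """Diameter (mm) at arclength ``s`` (mm), linear interpolation."""
        return np.interp(s, self.samples_s, self.samples_d)

    @classmethod
    def from_profile(cls, id: str, s: Iterable[float], d: Iterable[float],
                     role: str = "branch") -> "VesselSegment":
        s = tuple(float(x) for x in s)
        d = tuple(float(x) for x in d)
        return cls(id=id, length=s[-1], samples_s=s, samples_d=d, role=role)

    @classmethod
    def tapered(cls, id: str, length: float, d_start: float, d_end: float,
                role: str = "branch", n_samples: int = 2) -> "VesselSegment":
        s = np.linspace(0.0, length, max(2, n_samples))
        d = np.linspace(d_start, d_end, max(2, n_samples))
        return cls.from_profile(id, s, d, role=role)


@dataclass(frozen=True)
class Junction:
    parent: str
    s: float  # attachment arclength on the parent, mm
    child: str


@dataclass(frozen=True)
class StenosisSpec:
    """Idealized concentric stenosis on the trunk.

    ds is the diameter stenosis fraction (0.55 means a 55% DS), ``length``
    the axial extent in mm, ``center_s`` the throat arclength on the trunk.
    """

    ds: float
    length: float
    center_s: float
    shape: str = "cosine"  # cosine | trapezoid

    def __post_init__(self) -> None:
        if not 0 <= self.ds < 1:
            raise GeometryError(f"ds must be in [0, 1), got {self.ds}")
        if self.length <= 0:
            raise GeometryError("stenosis length must be positive")
        if self.shape not in ("cosine", "trapezoid"):
            raise GeometryError(f"unknown stenosis shape {self.shape!r}")

    @property
    def s_start(self) -> float:
        return self.center_s - self.length / 2.0

    @property
    def s_end(self) -> float:
        return self.center_s + self.length / 2.0

    def window(self, s: np.ndarray) -> np.ndarray:
        """Narrowing window w(s) in [0, 1]; 1 at the throat, 0 outside."""
        s = np.asarray(s, dtype=float)
        x = (s - self.s_start) / self.length  # 0..1 across the extent
        inside = (x >= 0.0) & (x <= 1.0)
        w = np.zeros_like(s)
        if self.shape == "cosine":
            if self.length > 4.0:
                # flat throat over the central 20% of longer lesions
                ramp = 0.4
                xi = np.clip(np.where(x < 0.5, x / ramp, (1.0 - x) / ramp), 0.0, 1.0)
                w_in = 0.5 * (1.0 - np.cos(np.pi * xi))
            else:
                w_in = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
        else:  # trapezoid: linear ramps over the outer 25% on each side
            ramp = 0.25
            xi = np.clip(np.where(x < 0.5, x / ramp, (1.0 - x) / ramp), 0.0, 1.0)
            w_in = xi
        w[inside] = w_in[inside]
        return w


@dataclass(frozen=True)
class CoronaryTree:
    segments: tuple[VesselSegment, ...]
    junctions: tuple[Junction, ...]
    inlet: str
    outlets: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups ---------------------------------------------------------
    def segment(self, seg_id: str) -> VesselSegment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise GeometryError(f"no segment {seg_id!r} in tree")

    @property
    def trunk(self) -> VesselSegment:
        return self.segment(self.inlet)

    def children_of(self, seg_id: str) -> list[Junction]:
        return sorted((j for j in self.junctions if j.parent == seg_id), key=lambda j: j.s)

    def locations(self) -> dict[str, float]:
        return dict(self.metadata.get("locations", {}))

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        ids = [seg.id for seg in self.segments]
        if len(set(ids)) != len(ids):
            raise GeometryError("duplicate segment ids")
        if self.inlet not in ids:
            raise GeometryError(f"inlet segment {self.inlet!r} not found")
        parent_of: dict[str, str] = {}
        for j in self.junctions:
            if j.parent not in ids or j.child not in ids:
                raise GeometryError(f"junction references unknown segment: {j}")
            if j.child in parent_of:
                raise GeometryError(f"segment {j.child!r} has more than one parent")
            if j.child == self.inlet:
                raise GeometryError("inlet segment cannot be a junction child")
            parent = self.segment(j.parent)
            if not 0 < j.s < parent.length:
                raise GeometryError(
                    f"junction attachment s={j.s} outside parent {j.parent!r} "
                    f"(length {parent.length})")
            parent_of[j.child] = j.parent
        # acyclic, single root: walk up from every segment
        for seg_id in ids:
            seen = set()
            cur = seg_id
            while cur in parent_of:
                if cur in seen:
                    raise GeometryError("cycle detected in junctions")
                seen.add(cur)
                cur = parent_of[cur]
            if cur != self.inlet:
                raise GeometryError(f"segment {seg_id!r} not connected to the inlet")
        # every non-trunk terminal segment appears exactly once in outlets
        parents = {j.parent for j in self.junctions}
        if len(set(self.outlets)) != len(self.outlets):
            raise GeometryError("duplicate outlet ids")
        for out in self.outlets:
            if out not in ids:
                raise GeometryError(f"outlet {out!r} not a segment")
        missing = {i for i in ids if i not in parents} - set(self.outlets)
        # non-trunk terminal segments must be outlets
        missing -= {self.inlet}
        if missing:
            raise GeometryError(f"terminal segments missing from outlets: {sorted(missing)}")


@dataclass(frozen=True)
class EmulatorConfig:
    """Dimensions of the emulated porcine LAD.

    The real animal's dimensions are unpublished; these documented defaults
    satisfy every stated anatomical constraint (trunk >= 2 mm everywhere,
    branches >= 1 mm, monotone taper) and give physiologic Murray splits.
    """

    trunk_length_mm: float = 100.0
    trunk_inlet_diameter_mm: float = 3.5
    trunk_outlet_diameter_mm: float = 2.0
    branch_positions_mm: tuple[float, ...] = DEFAULT_BRANCH_POSITIONS_MM
    branch_diameters_mm: tuple[float, ...] = DEFAULT_BRANCH_DIAMETERS_MM
    branch_length_mm: float = 20.0
    locations_mm: dict = field(default_factory=lambda: dict(DEFAULT_LOCATIONS_MM))
    trunk_samples: int = 201

    def __post_init__(self) -> None:
        if len(self.branch_positions_mm) != len(self.branch_diameters_mm):
            raise GeometryError("branch positions and diameters must have equal length")


def build_porcine_lad_emulator(config: EmulatorConfig | None = None) -> CoronaryTree:
    """Build the deterministic porcine-LAD emulator tree.

    One tapering trunk plus (by default) 7 primary branches named "a"-"g"
    proximal to distal; outlets are the 7 branch ends plus the distal trunk.
    """
    cfg = config or EmulatorConfig()
    if cfg.trunk_outlet_diameter_mm > cfg.trunk_inlet_diameter_mm:
        raise GeometryError("trunk taper must be monotone (inlet diameter >= outlet diameter)")
    if min(cfg.trunk_inlet_diameter_mm, cfg.trunk_outlet_diameter_mm) < 2.0:
        raise GeometryError("trunk diameter must be >= 2 mm over its full length")
    if cfg.branch_diameters_mm and min(cfg.branch_diameters_mm) < 1.0:
        raise GeometryError("every branch diameter must be >= 1 mm")
    trunk = VesselSegment.tapered(
        "trunk", cfg.trunk_length_mm, cfg.trunk_inlet_diameter_mm,
        cfg.trunk_outlet_diameter_mm, role="trunk", n_samples=cfg.trunk_samples)

    names = "abcdefghijklmnopqrstuvwxyz"
    segments = [trunk]
    junctions = []
    for i, (pos, dia) in enumerate(zip(cfg.branch_positions_mm, cfg.branch_diameters_mm)):
        if not 0 < pos < cfg.trunk_length_mm:
            raise GeometryError(f"branch position {pos} outside trunk")
        name = names[i]
        segments.append(VesselSegment.tapered(name, cfg.branch_length_mm, dia, dia))
        junctions.append(Junction(parent="trunk", s=float(pos), child=name))

    outlets = tuple(names[i] for i in range(len(cfg.branch_positions_mm))) + ("trunk",)
    locations = dict(cfg.locations_mm)
    for loc, s in locations.items():
        if not 0 < s < cfg.trunk_length_mm:
            raise GeometryError(f"location {loc!r} arclength {s} outside trunk")
    order = sorted(locations, key=locations.get)
    if order != sorted(locations):
        raise GeometryError("locations must be ordered proximal->distal by name")
    return CoronaryTree(
        segments=tuple(segments),
        junctions=tuple(junctions),
        inlet="trunk",
        outlets=outlets,
        metadata={"locations": locations, "emulator": "porcine_lad"},
    )


def insert_stenosis(tree: CoronaryTree, spec: StenosisSpec,
                    n_extent_samples: int = 201) -> CoronaryTree:
    """Return a new tree with an idealized stenosis narrowing the trunk.

    The original tree is not mutated. The throat sample is placed exactly
    at ``center_s`` so the throat diameter is exactly (1 - ds) times the
    local normal diameter. The stenotic extent must not overlap any
    junction attachment point.
    """
    trunk = tree.trunk
    if spec.s_start < 0 or spec.s_end > trunk.length:
        raise GeometryError(
            f"stenotic extent [{spec.s_start}, {spec.s_end}] outside trunk [0, {trunk.length}]")
    for j in tree.children_of(tree.inlet):
        if spec.s_start <= j.s <= spec.s_end:
            raise GeometryError(
                f"stenotic extent [{spec.s_start}, {spec.s_end}] overlaps the "
                f"junction of branch {j.child!r} at s={j.s}")
    if spec.ds == 0.0:
        return tree

    s_extent = np.linspace(spec.s_start, spec.s_end, n_extent_samples)
    if spec.center_s not in s_extent:
        s_extent = np.sort(np.append(s_extent, spec.center_s))
    s_old = np.asarray(trunk.samples_s)
    keep = (s_old < spec.s_start) | (s_old > spec.s_end)
    s_new = np.unique(np.concatenate([s_old[keep], s_extent]))
    d_normal = trunk.diameter(s_new)
    w = StenosisSpec.window(spec, s_new)
    d_new = d_normal * (1.0 - spec.ds * w)
    new_trunk = VesselSegment.from_profile(trunk.id, s_new, d_new, role=trunk.role)
    segments = tuple(new_trunk if seg.id == trunk.id else seg for seg in tree.segments)
    meta = dict(tree.metadata)
    meta["stenosis"] = {"ds": spec.ds, "length": spec.length,
                        "center_s": spec.center_s, "shape": spec.shape}
    return replace(tree, segments=segments, metadata=meta)


def make_stenosed_tube(diameter_mm: float, ds: float, stenosis_length_mm: float,
                       pad_upstream_diam: float = 3.0, pad_downstream_diam: float = 10.0,
                       shape: str = "cosine", n_samples: int = 241,
                       ) -> tuple[VesselSegment, StenosisSpec]:
    """Single straight tube with a centered idealized stenosis and entry/exit
    padding (in tube diameters) so an outflow boundary cannot clip the
    recirculation zone. Returns the narrowed segment and the local spec."""
    pad_up = pad_upstream_diam * diameter_mm
    pad_down = pad_downstream_diam * diameter_mm
    length = pad_up + stenosis_length_mm + pad_down
    center = pad_up + stenosis_length_mm / 2.0
    spec = StenosisSpec(ds=ds, length=stenosis_length_mm, center_s=center, shape=shape)
    s = np.union1d(np.linspace(0.0, length, n_samples),
                   np.linspace(spec.s_start, spec.s_end, 161))
    s = np.union1d(s, [spec.center_s])
    d = diameter_mm * (1.0 - ds * spec.window(s))
    return VesselSegment.from_profile("stenosed_tube", s, d), spec


def spec_at_location(tree: CoronaryTree, ds: float, length_mm: float,
                     location: str, shape: str = "cosine") -> StenosisSpec:
    """Build a :class:`StenosisSpec` centered at a named trunk location."""
    locs = tree.locations()
    if location not in locs:
        raise GeometryError(f"location {location!r} not in tree metadata "
                            f"(known: {sorted(locs)})")
    return StenosisSpec(ds=ds, length=length_mm, center_s=locs[location], shape=shape)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def tree_to_dict(tree: CoronaryTree) -> dict:
    return {
        "version": TREE_SCHEMA_VERSION,
        "units": {"length": "mm"},
        "segments": [
            {"id": seg.id, "role": seg.role, "length": seg.length,
             "profile": [[float(s), float(d)] for s, d in zip(seg.samples_s, seg.samples_d)]}
            for seg in tree.segments
        ],
        "junctions": [{"parent": j.parent, "s": j.s, "child": j.child}
                      for j in tree.junctions],
        "inlet": tree.inlet,
        "outlets": list(tree.outlets),
        "metadata": tree.metadata,
    }


def tree_from_dict(data: dict) -> CoronaryTree:
    for key in ("segments", "junctions", "inlet", "outlets"):
        if key not in data:
            raise GeometryError(f"tree document missing required key $.{key}")
    segments = []
    for i, seg in enumerate(data["segments"]):
        for key in ("id", "role", "length", "profile"):
            if key not in seg:
                raise GeometryError(f"missing key $.segments[{i}].{key}")
        prof = np.asarray(seg["profile"], dtype=float)
        if prof.ndim != 2 or prof.shape[1] != 2:
            raise GeometryError(f"$.segments[{i}].profile must be a list of [s, d] pairs")
        segments.append(VesselSegment(
            id=seg["id"], role=seg["role"], length=float(seg["length"]),
            samples_s=tuple(prof[:, 0]), samples_d=tuple(prof[:, 1])))
    junctions = tuple(Junction(parent=j["parent"], s=float(j["s"]), child=j["child"])
                      for j in data["junctions"])
    return CoronaryTree(
        segments=tuple(segments), junctions=junctions,
        inlet=data["inlet"], outlets=tuple(data["outlets"]),
        metadata=data.get("metadata", {}))


def write_tree(tree: CoronaryTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=1))


def read_tree(path: str | Path) -> CoronaryTree:
    return tree_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Centerline export
# ---------------------------------------------------------------------------

def _centerline_points(tree: CoronaryTree) -> list[tuple[str, float, float, float]]:
    """(segment id, s, x-proxy, diameter) rows; x-proxy is the path length
    from the tree inlet to the point (branches offset from their junction)."""
    if not tree.segments:
        raise GeometryError("empty tree")
    offset = {tree.inlet: 0.0}
    ordered = [tree.inlet]
    while ordered:
        nxt = []
        for seg_id in ordered:
            for j in tree.children_of(seg_id):
                offset[j.child] = offset[seg_id] + j.s
                nxt.append(j.child)
        ordered = nxt
    rows = []
    for seg in tree.segments:
        base = offset[seg.id]
        for s, d in zip(seg.samples_s, seg.samples_d):
            rows.append((seg.id, float(s), base + float(s), float(d)))
    return rows


def export_centerline(tree: CoronaryTree, path: str | Path, format: str = "csv") -> None:
    """Export per-point centerline records as CSV or a legacy VTK polyline."""
    rows = _centerline_points(tree)
    path = Path(path)
    if format == "csv":
        lines = ["segment,s_mm,diameter_mm"]
        lines += [f"{seg},{s:.6g},{d:.6g}" for seg, s, _x, d in rows]
        path.write_text("\n".join(lines) + "\n")
    elif format == "vtk-polyline":
        # one polyline per segment, laid out along x with branches offset in y
        seg_rows: dict[str, list[tuple[float, float, float]]] = {}
        y_index = {seg.id: i for i, seg in enumerate(tree.segments)}
        for seg, s, x, d in rows:
            y = 0.0 if seg == tree.inlet else 5.0 * y_index[seg]
            seg_rows.setdefault(seg, []).append((x, y, d))
        npts = sum(len(v) for v in seg_rows.values())
        out = ["# vtk DataFile Version 3.0", "ffrct centerline", "ASCII",
               "DATASET POLYDATA", f"POINTS {npts} float"]
        for pts in seg_rows.values():
            out += [f"{x:.6g} {y:.6g} 0" for x, y, _d in pts]
        nlines = len(seg_rows)
        out.append(f"LINES {nlines} {nlines + npts}")
        idx = 0
        for pts in seg_rows.values():
            out.append(" ".join([str(len(pts))] + [str(idx + k) for k in range(len(pts))]))
            idx += len(pts)
        out += [f"POINT_DATA {npts}", "SCALARS diameter_mm float 1", "LOOKUP_TABLE default"]
        for pts in seg_rows.values():
            out += [f"{d:.6g}" for _x, _y, d in pts]
        path.write_text("\n".join(out) + "\n")
    else:
        raise GeometryError(f"unknown centerline export format {format!r}")
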