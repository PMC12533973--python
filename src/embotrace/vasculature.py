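"""Synthetic heart-to-brain arterial tree with parameterized carotid stenosis.

This module generates the vascular geometry over which all flow and embolus
transport computations run: a single-inlet (aortic root), 11-outlet arterial
network spanning the aortic arch, the cervical vessels (common/internal/
external carotids, vertebrals) and a complete Circle of Willis (anterior
communicating artery, both posterior communicators, both P1 segments).

Stenoses are parameterized by the NASCET diameter criterion
``severity = (1 - d_min / d_reference) * 100`` and imposed on the proximal
internal carotid as a smooth cosine taper whose length grows proportionally
with severity.  A model family pairs one mild severity {10, 25, 40} with one
moderate/severe severity {50, 70, 85} on each side (18 bilateral models) and
adds 12 contralateral-carotid-occlusion (CCO) models with one carotid fully
occluded.  Each non-CCO model admits three embolus release sources (left
carotid, right carotid, cardiogenic at the aortic root) and each CCO model
two, for 78 experiments at default settings.

Coordinates are millimetres, right-handed, patient-left = +x, anterior = +y,
cranial = +z.  Arc lengths are measured from the proximal node of a segment.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ConfigurationError",
    "SegmentGeometry",
    "NetworkTopology",
    "StenosisSpec",
    "ModelSpec",
    "ExperimentSpec",
    "DEFAULT_TEMPLATE",
    "build_baseline_network",
    "nascet_severity",
    "stenosis_length",
    "apply_stenosis",
    "build_model_network",
    "enumerate_models",
    "enumerate_experiments",
    "mirrored_network",
    "write_vtp_polylines",
]


class ConfigurationError(ValueError):
    """Raised when a geometry/family configuration is inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

MILD_SEVERITIES = (10.0, 25.0, 40.0)
SEVERE_SEVERITIES = (50.0, 70.0, 85.0)

#: Segments on which a stenosis may be imposed.
CAROTID_SEGMENTS = frozenset(
    {
        "l_internal_carotid",
        "r_internal_carotid",
        "l_common_carotid",
        "r_common_carotid",
    }
)

CEREBRAL_OUTLETS = ("l_mca", "r_mca", "l_aca", "r_aca", "l_pca", "r_pca")


@dataclass
class StenosisSpec:
    """One carotid stenosis: side, NASCET severity and throat parameterization."""

    side: str  # "left" | "right"
    severity_nascet: float  # percent, in [0, 100]
    site_segment: str = ""  # default resolved to the proximal ICA of `side`
    length: float = 0.0  # mm; 0 means "use the proportional default rule"
    s_start: float = 8.0  # mm from the proximal node where the taper begins
    length_factor: float = 0.5  # k in L = k * (severity/100) * L_ref

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"stenosis side must be left/right, got {self.side!r}")
        if not (0.0 <= self.severity_nascet <= 100.0):
            raise ConfigurationError(
                f"NASCET severity must lie in [0, 100], got {self.severity_nascet}"
            )
        if not self.site_segment:
            self.site_segment = f"{self.side[0]}_internal_carotid"

    @property
    def occluded(self) -> bool:
        return self.severity_nascet >= 100.0


@dataclass
class SegmentGeometry:
    """A vessel segment: centerline polyline, radius profile and end nodes."""

    id: str
    name: str
    points: np.ndarray  # (n, 3) mm
    radii: np.ndarray  # (n,) mm
    proximal_node: str
    distal_node: str
    occluded: bool = False
    stenosis: Optional[StenosisSpec] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ConfigurationError(f"segment {self.id}: points must be (n, 3)")
        if len(self.radii) != len(self.points):
            raise ConfigurationError(f"segment {self.id}: radii/points length mismatch")
        if self.proximal_node == self.distal_node:
            raise ConfigurationError(f"segment {self.id}: must connect two distinct nodes")
        ds = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(ds <= 0):
            raise ConfigurationError(f"segment {self.id}: arc length not strictly increasing")
        if not self.occluded and np.any(self.radii <= 0):
            raise ConfigurationError(f"segment {self.id}: non-positive radius on patent segment")

    @property
    def arclengths(self) -> np.ndarray:
        ds = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(ds)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def radius_at(self, s: float) -> float:
        return float(np.interp(s, self.arclengths, self.radii))

    def point_at(self, s: float) -> np.ndarray:
        sl = self.arclengths
        return np.stack([np.interp(s, sl, self.points[:, k]) for k in range(3)])

    def copy(self) -> "SegmentGeometry":
        return SegmentGeometry(
            id=self.id,
            name=self.name,
            points=self.points.copy(),
            radii=self.radii.copy(),
            proximal_node=self.proximal_node,
            distal_node=self.distal_node,
            occluded=self.occluded,
            stenosis=copy.deepcopy(self.stenosis),
        )


@dataclass
class NetworkTopology:
    """The synthetic vessel tree: segments, junctions, inlet and 11 outlets."""

    segments: Dict[str, SegmentGeometry]
    inlet: str
    outlets: Dict[str, str]  # outlet label -> node id
    hemisphere_map: Dict[str, str]  # outlet label -> {"left", "right", "none"}
    node_positions: Dict[str, np.ndarray] = field(default_factory=dict)

    def graph(self, exclude_occluded: bool = False) -> nx.Graph:
        g = nx.Graph()
        for seg in self.segments.values():
            if exclude_occluded and seg.occluded:
                continue
            g.add_edge(seg.proximal_node, seg.distal_node, id=seg.id)
        return g

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_connected(g):
            raise ConfigurationError("network graph is not connected")
        if len(self.outlets) != 11:
            raise ConfigurationError(f"expected 11 outlets, found {len(self.outlets)}")
        for required in ("acoa", "l_pcoa", "r_pcoa", "l_p1", "r_p1"):
            if required not in self.segments:
                raise ConfigurationError(
                    f"complete Circle of Willis requires segment {required!r}"
                )

    def node_segments(self, node: str) -> List[str]:
        return [s.id for s in self.segments.values() if node in (s.proximal_node, s.distal_node)]

    def outlet_of_node(self, node: str) -> Optional[str]:
        for label, n in self.outlets.items():
            if n == node:
                return label
        return None

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            segments={k: s.copy() for k, s in self.segments.items()},
            inlet=self.inlet,
            outlets=dict(self.outlets),
            hemisphere_map=dict(self.hemisphere_map),
            node_positions={k: np.array(v) for k, v in self.node_positions.items()},
        )

    def to_json(self) -> str:
        payload = {
            "inlet": self.inlet,
            "outlets": self.outlets,
            "hemisphere_map": self.hemisphere_map,
            "segments": {
                sid: {
                    "name": s.name,
                    "points": (np.round(s.points, 9) + 0.0).tolist(),
                    "radii": (np.round(s.radii, 9) + 0.0).tolist(),
                    "proximal_node": s.proximal_node,
                    "distal_node": s.distal_node,
                    "occluded": s.occluded,
                }
                for sid, s in sorted(self.segments.items())
            },
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetworkTopology":
        payload = json.loads(text)
        segs = {
            sid: SegmentGeometry(
                id=sid,
                name=d["name"],
                points=np.array(d["points"]),
                radii=np.array(d["radii"]),
                proximal_node=d["proximal_node"],
                distal_node=d["distal_node"],
                occluded=d["occluded"],
            )
            for sid, d in payload["segments"].items()
        }
        return cls(
            segments=segs,
            inlet=payload["inlet"],
            outlets=payload["outlets"],
            hemisphere_map=payload["hemisphere_map"],
        )


@dataclass(frozen=True)
class ModelSpec:
    """One stenosis-severity pairing, labelled e.g. ``10L50R``."""

    left_severity: float
    right_severity: float

    @property
    def label(self) -> str:
        return f"{int(round(self.left_severity))}L{int(round(self.right_severity))}R"

    @property
    def is_cco(self) -> bool:
        return self.left_severity >= 100.0 or self.right_severity >= 100.0

    @property
    def occluded_side(self) -> Optional[str]:
        if self.left_severity >= 100.0:
            return "left"
        if self.right_severity >= 100.0:
            return "right"
        return None


@dataclass(frozen=True)
class ExperimentSpec:
    """One (model, release source) simulation unit."""

    model: ModelSpec
    source: str  # "left_carotid" | "right_carotid" | "cardiogenic"
    n_emboli: int = 5500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("left_carotid", "right_carotid", "cardiogenic"):
            raise ConfigurationError(f"unknown release source {self.source!r}")
        occl = self.model.occluded_side
        if occl is not None and self.source == f"{occl}_carotid":
            raise ConfigurationError(
                f"model {self.model.label}: cannot release from occluded {occl} carotid"
            )

    @property
    def label(self) -> str:
        return f"{self.model.label}:{self.source}"


# ---------------------------------------------------------------------------
# Baseline geometry template
# ---------------------------------------------------------------------------

# Node coordinates (mm).  Left-right symmetric except the aortic-arch branch
# ordering: the brachiocephalic trunk branches first and feeds the right
# common carotid and subclavian, while the left common carotid and subclavian
# originate directly (and slightly later) from the arch.  This is the only
# built-in asymmetry, so any right-preferential recruitment of cardiogenic
# emboli emerges from branching geometry.
_NODES: Dict[str, Tuple[float, float, float]] = {
    "inlet": (0.0, 0.0, 0.0),
    "arch_bca": (-7.0, 10.0, 48.0),
    "arch_lcca": (0.0, 12.0, 55.0),
    "arch_lsub": (8.0, 8.0, 54.0),
    "desc_out": (18.0, -26.0, -45.0),
    "bca_bif": (-22.0, 3.0, 80.0),
    "r_sub_vert": (-38.0, -2.0, 76.0),
    "r_sub_out": (-66.0, -6.0, 68.0),
    "l_sub_vert": (38.0, -10.0, 74.0),
    "l_sub_out": (66.0, -14.0, 66.0),
    "r_car_bif": (-20.0, 8.0, 160.0),
    "l_car_bif": (20.0, 8.0, 160.0),
    "r_eca_out": (-25.0, 20.0, 206.0),
    "l_eca_out": (25.0, 20.0, 206.0),
    "r_ica_c7": (-14.0, -4.0, 231.0),
    "l_ica_c7": (14.0, -4.0, 231.0),
    "r_ica_term": (-14.0, 0.0, 236.0),
    "l_ica_term": (14.0, 0.0, 236.0),
    "vb_junction": (0.0, -32.0, 204.0),
    "bas_top": (0.0, -24.0, 234.0),
    "r_pca_j": (-9.0, -26.0, 237.0),
    "l_pca_j": (9.0, -26.0, 237.0),
    "r_aca_j": (-3.0, 10.0, 240.0),
    "l_aca_j": (3.0, 10.0, 240.0),
    "r_mca_out": (-42.0, -2.0, 242.0),
    "l_mca_out": (42.0, -2.0, 242.0),
    "r_aca_out": (-4.0, 16.0, 266.0),
    "l_aca_out": (4.0, 16.0, 266.0),
    "r_pca_out": (-28.0, -34.0, 245.0),
    "l_pca_out": (28.0, -34.0, 245.0),
}

# Segment defs: (proximal node, distal node, proximal radius, distal radius,
# via control points).  Radii in mm; centerlines are splined through the
# via points for smooth tangents.
_SEGMENTS: Dict[str, dict] = {
    "aortic_root": dict(
        nodes=("inlet", "arch_bca"), r=(12.5, 11.5),
        via=[(0.0, 2.0, 15.0), (-3.0, 7.0, 32.0)],
    ),
    "aortic_arch_i": dict(nodes=("arch_bca", "arch_lcca"), r=(11.5, 11.0), via=[]),
    "aortic_arch_ii": dict(nodes=("arch_lcca", "arch_lsub"), r=(11.0, 10.5), via=[]),
    "descending_aorta": dict(
        nodes=("arch_lsub", "desc_out"),
        r=(10.5, 9.0),
        via=[(16.0, -6.0, 40.0), (18.0, -20.0, 10.0), (18.0, -24.0, -15.0)],
    ),
    "brachiocephalic": dict(nodes=("arch_bca", "bca_bif"), r=(6.5, 5.5), via=[]),
    "r_subclavian": dict(nodes=("bca_bif", "r_sub_vert"), r=(4.4, 4.2), via=[]),
    "r_subclavian_outlet": dict(nodes=("r_sub_vert", "r_sub_out"), r=(4.2, 4.0), via=[]),
    "l_subclavian": dict(nodes=("arch_lsub", "l_sub_vert"), r=(4.4, 4.2), via=[]),
    "l_subclavian_outlet": dict(nodes=("l_sub_vert", "l_sub_out"), r=(4.2, 4.0), via=[]),
    "r_common_carotid": dict(
        nodes=("bca_bif", "r_car_bif"), r=(3.6, 3.4), via=[(-20.0, 6.0, 120.0)]
    ),
    "l_common_carotid": dict(
        nodes=("arch_lcca", "l_car_bif"), r=(3.6, 3.4), via=[(20.0, 6.0, 120.0)]
    ),
    "r_external_carotid": dict(
        nodes=("r_car_bif", "r_eca_out"), r=(2.1, 1.8), via=[]
    ),
    "l_external_carotid": dict(
        nodes=("l_car_bif", "l_eca_out"), r=(2.1, 1.8), via=[]
    ),
    # The cervical ICA rises nearly straight, then the cavernous siphon
    # executes an S of tight bends before the communicating (C7) segment;
    # the bends drive the Dean mixing that stirs the cross-section.
    "r_internal_carotid": dict(
        nodes=("r_car_bif", "r_ica_c7"),
        r=(2.5, 2.1),
        via=[(-17.0, 4.0, 190.0), (-16.0, 6.0, 204.0), (-15.2, 0.5, 217.0),
             (-14.5, -1.5, 225.0)],
    ),
    "l_internal_carotid": dict(
        nodes=("l_car_bif", "l_ica_c7"),
        r=(2.5, 2.1),
        via=[(17.0, 4.0, 190.0), (16.0, 6.0, 204.0), (15.2, 0.5, 217.0),
             (14.5, -1.5, 225.0)],
    ),
    "r_ica_terminal": dict(nodes=("r_ica_c7", "r_ica_term"), r=(2.1, 1.9), via=[]),
    "l_ica_terminal": dict(nodes=("l_ica_c7", "l_ica_term"), r=(2.1, 1.9), via=[]),
    "r_vertebral": dict(
        nodes=("r_sub_vert", "vb_junction"), r=(1.9, 1.8), via=[(-10.0, -22.0, 140.0)]
    ),
    "l_vertebral": dict(
        nodes=("l_sub_vert", "vb_junction"), r=(1.9, 1.8), via=[(10.0, -22.0, 140.0)]
    ),
    "basilar": dict(nodes=("vb_junction", "bas_top"), r=(1.7, 1.6), via=[]),
    "r_p1": dict(nodes=("bas_top", "r_pca_j"), r=(1.1, 1.1), via=[]),
    "l_p1": dict(nodes=("bas_top", "l_pca_j"), r=(1.1, 1.1), via=[]),
    "r_pcoa": dict(
        nodes=("r_ica_c7", "r_pca_j"), r=(0.7, 0.7), via=[(-12.5, -12.0, 230.5)]
    ),
    "l_pcoa": dict(
        nodes=("l_ica_c7", "l_pca_j"), r=(0.7, 0.7), via=[(12.5, -12.0, 230.5)]
    ),
    "r_p2": dict(nodes=("r_pca_j", "r_pca_out"), r=(1.05, 1.0), via=[]),
    "l_p2": dict(nodes=("l_pca_j", "l_pca_out"), r=(1.05, 1.0), via=[]),
    "r_m1": dict(nodes=("r_ica_term", "r_mca_out"), r=(1.45, 1.35), via=[]),
    "l_m1": dict(nodes=("l_ica_term", "l_mca_out"), r=(1.45, 1.35), via=[]),
    "r_a1": dict(nodes=("r_ica_term", "r_aca_j"), r=(1.15, 1.1), via=[]),
    "l_a1": dict(nodes=("l_ica_term", "l_aca_j"), r=(1.15, 1.1), via=[]),
    # AcoA proximal node is on the right: positive flow means right -> left.
    "acoa": dict(nodes=("r_aca_j", "l_aca_j"), r=(0.7, 0.7), via=[]),
    "r_a2": dict(nodes=("r_aca_j", "r_aca_out"), r=(1.1, 1.05), via=[]),
    "l_a2": dict(nodes=("l_aca_j", "l_aca_out"), r=(1.1, 1.05), via=[]),
}

_OUTLETS: Dict[str, str] = {
    "descending_aorta": "desc_out",
    "r_subclavian": "r_sub_out",
    "l_subclavian": "l_sub_out",
    "r_eca": "r_eca_out",
    "l_eca": "l_eca_out",
    "r_mca": "r_mca_out",
    "l_mca": "l_mca_out",
    "r_aca": "r_aca_out",
    "l_aca": "l_aca_out",
    "r_pca": "r_pca_out",
    "l_pca": "l_pca_out",
}

_HEMISPHERES: Dict[str, str] = {
    label: ("left" if label.startswith("l_") and label in
            ("l_mca", "l_aca", "l_pca") else
            "right" if label.startswith("r_") and label in
            ("r_mca", "r_aca", "r_pca") else "none")
    for label in _OUTLETS
}

_ANATOMICAL_NAMES: Dict[str, str] = {
    "aortic_root": "aortic root",
    "aortic_arch_i": "aortic arch",
    "aortic_arch_ii": "aortic arch",
    "descending_aorta": "descending aorta",
    "brachiocephalic": "brachiocephalic",
    "r_subclavian": "R subclavian",
    "l_subclavian": "L subclavian",
    "r_subclavian_outlet": "terminal outlet stub",
    "l_subclavian_outlet": "terminal outlet stub",
    "r_common_carotid": "R common carotid",
    "l_common_carotid": "L common carotid",
    "r_external_carotid": "R external carotid",
    "l_external_carotid": "L external carotid",
    "r_internal_carotid": "R internal carotid",
    "l_internal_carotid": "L internal carotid",
    "r_vertebral": "R vertebral",
    "l_vertebral": "L vertebral",
    "basilar": "basilar",
    "r_p1": "R P1",
    "l_p1": "L P1",
    "r_ica_terminal": "R terminal internal carotid",
    "l_ica_terminal": "L terminal internal carotid",
    "r_pcoa": "R posterior communicator",
    "l_pcoa": "L posterior communicator",
    "r_p2": "terminal outlet stub",
    "l_p2": "terminal outlet stub",
    "r_m1": "R M1",
    "l_m1": "L M1",
    "r_a1": "R A1",
    "l_a1": "L A1",
    "acoa": "AcoA",
    "r_a2": "terminal outlet stub",
    "l_a2": "terminal outlet stub",
}

DEFAULT_TEMPLATE: dict = {
    "nodes": _NODES,
    "segments": _SEGMENTS,
    "outlets": _OUTLETS,
    "hemispheres": _HEMISPHERES,
    "spacing": 2.0,
    "carotid_spacing": 1.0,
    "symmetric_arch": False,
}


def _mirror_x(p: Sequence[float]) -> Tuple[float, float, float]:
    return (-p[0], p[1], p[2])


def _symmetrize_template(template: dict) -> dict:
    """Build a perfectly left-right symmetric variant of the template.

    Used by symmetry oracles.  The arch chain is replaced by a single midline
    junction from which twin brachiocephalic trunks branch to each side, each
    feeding the ipsilateral common carotid and subclavian; the descending
    aorta runs on the midline.  Sides are exact x-mirrors of each other.
    """
    t = copy.deepcopy(template)
    nodes, segs = t["nodes"], t["segments"]
    nodes["arch_mid"] = (0.0, 0.0, 56.0)
    nodes["desc_out"] = (0.0, -26.0, -45.0)
    nodes["bca_bif"] = (-22.0, 3.0, 80.0)
    nodes["lca_bif"] = _mirror_x(nodes["bca_bif"])
    nodes["l_sub_vert"] = _mirror_x(nodes["r_sub_vert"])
    nodes["l_sub_out"] = _mirror_x(nodes["r_sub_out"])
    nodes["l_car_bif"] = _mirror_x(nodes["r_car_bif"])
    for dead in ("arch_bca", "arch_lcca", "arch_lsub"):
        nodes.pop(dead, None)
    for dead in ("aortic_arch_i", "aortic_arch_ii"):
        segs.pop(dead, None)
    segs["aortic_root"] = dict(nodes=("inlet", "arch_mid"), r=(12.5, 11.0),
                               via=[(0.0, 3.0, 30.0)])
    segs["descending_aorta"] = dict(
        nodes=("arch_mid", "desc_out"), r=(10.5, 9.0),
        via=[(0.0, -18.0, 30.0), (0.0, -24.0, -5.0)],
    )
    segs["brachiocephalic"] = dict(nodes=("arch_mid", "bca_bif"), r=(6.5, 5.5), via=[])
    segs["l_brachiocephalic"] = dict(nodes=("arch_mid", "lca_bif"), r=(6.5, 5.5), via=[])
    segs["r_common_carotid"] = dict(segs["r_common_carotid"], nodes=("bca_bif", "r_car_bif"))
    # Mirror every right-side branch definition exactly onto the left.
    for rseg, lseg in (
        ("r_common_carotid", "l_common_carotid"),
        ("r_subclavian", "l_subclavian"),
        ("r_subclavian_outlet", "l_subclavian_outlet"),
        ("r_vertebral", "l_vertebral"),
    ):
        rdef = segs[rseg]
        segs[lseg] = dict(
            nodes=tuple(_swap_side(n) for n in rdef["nodes"]),
            r=tuple(rdef["r"]),
            via=[_mirror_x(v) for v in rdef["via"]],
        )
    t["symmetric_arch"] = True
    return t


def _resample_polyline(
    points: np.ndarray, radii: np.ndarray, spacing: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Spline-resample a polyline at approximately uniform arc-length spacing."""
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    ds = np.linalg.norm(np.diff(points, axis=0), axis=1)
    chord = np.concatenate([[0.0], np.cumsum(ds)])
    total = chord[-1]
    n_out = max(int(np.ceil(total / spacing)) + 1, 5)
    s_new = np.linspace(0.0, total, n_out)
    if len(points) >= 3:
        spl = CubicSpline(chord, points, axis=0, bc_type="natural")
        pts = spl(s_new)
    else:
        pts = np.stack([np.interp(s_new, chord, points[:, k]) for k in range(3)], axis=1)
    rad = np.interp(s_new, chord, radii)
    return pts, rad


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_baseline_network(template_config: Optional[dict] = None) -> NetworkTopology:
    """Build the baseline (no-stenosis) heart-to-brain network.

    ``template_config`` entries override :data:`DEFAULT_TEMPLATE`; setting a
    segment to ``None`` removes it, which is a configuration error for the
    Circle-of-Willis communicators (the baseline requires a complete CoW).
    Deterministic for a given config.
    """
    template = copy.deepcopy(DEFAULT_TEMPLATE)
    if template_config:
        for key, value in template_config.items():
            if key in ("nodes", "segments") and isinstance(value, dict):
                template[key] = {**template[key], **value}
            else:
                template[key] = value
    if template.get("symmetric_arch"):
        template = _symmetrize_template(template)

    removed = [sid for sid, sdef in template["segments"].items() if sdef is None]
    for sid in removed:
        if sid in ("acoa", "l_pcoa", "r_pcoa", "l_p1", "r_p1"):
            raise ConfigurationError(
                f"segment {sid!r} removed: baseline requires a complete Circle of Willis"
            )
        del template["segments"][sid]

    nodes = {k: np.asarray(v, dtype=float) for k, v in template["nodes"].items()}
    segments: Dict[str, SegmentGeometry] = {}
    for sid, sdef in template["segments"].items():
        try:
            n_prox, n_dist = sdef["nodes"]
            r_prox, r_dist = sdef["r"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"segment {sid!r}: malformed definition") from exc
        for n in (n_prox, n_dist):
            if n not in nodes:
                raise ConfigurationError(f"segment {sid!r}: missing node {n!r} in config")
        ctrl = [nodes[n_prox]] + [np.asarray(v, float) for v in sdef.get("via", [])] + [nodes[n_dist]]
        ctrl_r = np.linspace(r_prox, r_dist, len(ctrl))
        spacing = (
            template["carotid_spacing"]
            if ("carotid" in sid or sid in ("r_m1", "l_m1", "r_a1", "l_a1", "acoa",
                                            "r_pcoa", "l_pcoa", "r_p1", "l_p1"))
            else template["spacing"]
        )
        pts, rad = _resample_polyline(np.stack(ctrl), ctrl_r, spacing)
        segments[sid] = SegmentGeometry(
            id=sid,
            name=_ANATOMICAL_NAMES.get(sid, sid),
            points=pts,
            radii=rad,
            proximal_node=n_prox,
            distal_node=n_dist,
        )

    net = NetworkTopology(
        segments=segments,
        inlet="inlet",
        outlets=dict(template["outlets"]),
        hemisphere_map=dict(template["hemispheres"]),
        node_positions=nodes,
    )
    net.validate()
    return net


def nascet_severity(r_min: float, r_ref: float) -> float:
    """NASCET percent severity from minimum and reference lumen radius.

    NASCET grades by diameter ratio, ``(1 - d_min/d_ref) * 100``, which equals
    the radius-ratio form used here.
    """
    if r_ref <= 0:
        raise ValueError("reference radius must be positive")
    if r_min < 0:
        raise ValueError("minimum radius cannot be negative")
    if r_min > r_ref:
        raise ValueError("minimum radius exceeds reference (negative severity)")
    return (1.0 - r_min / r_ref) * 100.0


def stenosis_length(severity: float, length_factor: float = 0.5,
                    reference_length: float = 20.0) -> float:
    """Stenosis length (mm), growing proportionally with severity.

    ``L = k * (severity / 100) * L_ref`` with configurable gain ``k``; a more
    severe stenosis disturbs a longer span of the artery.
    """
    if not (0.0 <= severity <= 100.0):
        raise ValueError("severity must lie in [0, 100]")
    return length_factor * (severity / 100.0) * reference_length


def apply_stenosis(network: NetworkTopology, spec: StenosisSpec) -> NetworkTopology:
    """Return a copy of ``network`` with one carotid stenosis imposed.

    The radius profile within the stenosis length follows a cosine taper down
    to ``r_ref * (1 - severity/100)`` at the throat; severity 100 flags the
    segment occluded (no flow, no release) while the rest of the network is
    untouched.
    """
    if spec.site_segment not in network.segments:
        raise ConfigurationError(f"site segment {spec.site_segment!r} not in network")
    if spec.site_segment not in CAROTID_SEGMENTS:
        raise ConfigurationError(
            f"stenosis site must be a carotid segment, got {spec.site_segment!r}"
        )
    out = network.copy()
    if spec.severity_nascet == 0.0:
        return out
    seg = out.segments[spec.site_segment]
    if spec.occluded:
        seg.occluded = True
        seg.stenosis = copy.deepcopy(spec)
        return out

    L_seg = seg.length
    L = spec.length if spec.length > 0 else stenosis_length(
        spec.severity_nascet, spec.length_factor, L_seg
    )
    s0 = spec.s_start
    if s0 + L > L_seg - 2.0:
        L = max(L_seg - 2.0 - s0, 1.0)
    s = seg.arclengths
    depth = spec.severity_nascet / 100.0
    mask = (s >= s0) & (s <= s0 + L)
    taper = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[mask] - s0) / L))
    seg.radii = seg.radii.copy()
    seg.radii[mask] = seg.radii[mask] * (1.0 - depth * taper)
    sten = copy.deepcopy(spec)
    sten.length = L
    seg.stenosis = sten
    return out


def build_model_network(baseline: NetworkTopology, model: ModelSpec,
                        **stenosis_kwargs) -> NetworkTopology:
    """Apply a model's left and right carotid severities to the baseline."""
    net = baseline
    for side, sev in (("left", model.left_severity), ("right", model.right_severity)):
        if sev > 0:
            net = apply_stenosis(net, StenosisSpec(side=side, severity_nascet=sev,
                                                   **stenosis_kwargs))
    return net


def enumerate_models(family_config: Optional[dict] = None) -> List[ModelSpec]:
    """Enumerate the stenosis model family.

    Bilateral set: every (mild, moderate/severe) pair on each side assignment
    (2 * |mild| * |severe| models).  CCO set: one fully occluded carotid paired
    with each mild and moderate/severe severity on the other side
    (2 * (|mild| + |severe|) models).  Defaults yield 30 models.
    """
    cfg = family_config or {}
    mild = tuple(float(v) for v in cfg.get("mild", MILD_SEVERITIES))
    severe = tuple(float(v) for v in cfg.get("severe", SEVERE_SEVERITIES))
    include_cco = bool(cfg.get("cco", True))
    if set(mild) & set(severe):
        raise ConfigurationError("mild and moderate/severe severity sets overlap")
    models: List[ModelSpec] = []
    for m in mild:
        for sv in severe:
            models.append(ModelSpec(left_severity=m, right_severity=sv))
            models.append(ModelSpec(left_severity=sv, right_severity=m))
    if include_cco:
        for sev in (*mild, *severe):
            models.append(ModelSpec(left_severity=100.0, right_severity=sev))
            models.append(ModelSpec(left_severity=sev, right_severity=100.0))
    labels = [m.label for m in models]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("model labels are not unique")
    return models


def enumerate_experiments(
    models: Iterable[ModelSpec],
    n_per_source: int = 5500,
    seed_policy: int = 0,
) -> List[ExperimentSpec]:
    """Expand models into (model, source) experiments with reproducible seeds.

    Non-CCO models admit left-carotid, right-carotid and cardiogenic releases;
    CCO models only the patent carotid and cardiogenic (78 experiments for the
    default 30-model family).
    """
    experiments: List[ExperimentSpec] = []
    i = 0
    for model in models:
        occl = model.occluded_side
        sources = ["left_carotid", "right_carotid", "cardiogenic"]
        if occl is not None:
            sources.remove(f"{occl}_carotid")
        for source in sources:
            seed = int(
                np.random.SeedSequence(entropy=seed_policy, spawn_key=(i,))
                .generate_state(1)[0] % (2**31)
            )
            experiments.append(
                ExperimentSpec(model=model, source=source, n_emboli=n_per_source, seed=seed)
            )
            i += 1
    return experiments


# ---------------------------------------------------------------------------
# Helpers: mirroring, export
# ---------------------------------------------------------------------------

def _swap_side(name: str) -> str:
    if name == "brachiocephalic":
        return "l_brachiocephalic"
    if name == "l_brachiocephalic":
        return "brachiocephalic"
    if name.startswith("l_"):
        return "r_" + name[2:]
    if name.startswith("r_"):
        return "l_" + name[2:]
    if name.startswith("lca_"):
        return "bca_" + name[4:]
    if name.startswith("bca_"):
        return "lca_" + name[4:]
    if name == "arch_bca":
        return "arch_lcca"
    if name == "arch_lcca":
        return "arch_bca"
    return name


def mirrored_network(network: NetworkTopology) -> NetworkTopology:
    """Mirror a network about the mid-sagittal plane (x -> -x, sides swapped).

    On a perfectly symmetric baseline, applying severity p on the left then
    mirroring is identical to applying p on the right.
    """
    segs: Dict[str, SegmentGeometry] = {}
    for sid, s in network.segments.items():
        pts = s.points.copy()
        pts[:, 0] *= -1.0
        nid = _swap_side(sid)
        if nid == sid and _swap_side(s.proximal_node) != s.proximal_node:
            # Midline segment (AcoA): restore canonical orientation.
            segs[nid] = SegmentGeometry(
                id=nid, name=s.name, points=pts[::-1].copy(),
                radii=s.radii[::-1].copy(), proximal_node=s.proximal_node,
                distal_node=s.distal_node, occluded=s.occluded,
                stenosis=copy.deepcopy(s.stenosis),
            )
            continue
        segs[nid] = SegmentGeometry(
            id=nid,
            name=_ANATOMICAL_NAMES.get(nid, nid),
            points=pts,
            radii=s.radii.copy(),
            proximal_node=_swap_side(s.proximal_node),
            distal_node=_swap_side(s.distal_node),
            occluded=s.occluded,
            stenosis=copy.deepcopy(s.stenosis),
        )
    return NetworkTopology(
        segments=segs,
        inlet=network.inlet,
        outlets={_swap_side(k): _swap_side(v) for k, v in network.outlets.items()},
        hemisphere_map={
            _swap_side(k): {"left": "right", "right": "left", "none": "none"}[v]
            for k, v in network.hemisphere_map.items()
        },
        node_positions={
            _swap_side(k): np.array([-v[0], v[1], v[2]])
            for k, v in network.node_positions.items()
        },
    )


def write_vtp_polylines(network: NetworkTopology, path: str) -> None:
    """Write segment centerlines as an ASCII VTP polyline file with radius data."""
    pts_all, radii_all, connectivity, offsets = [], [], [], []
    base = 0
    for seg in sorted(network.segments.values(), key=lambda s: s.id):
        n = len(seg.points)
        pts_all.append(seg.points)
        radii_all.append(seg.radii)
        connectivity.extend(range(base, base + n))
        offsets.append(base + n)
        base += n
    pts = np.vstack(pts_all)
    rad = np.concatenate(radii_all)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
        fh.write("  <PolyData>\n")
        fh.write(
            f'    <Piece NumberOfPoints="{len(pts)}" NumberOfLines="{len(offsets)}">\n'
        )
        fh.write('      <Points>\n        <DataArray type="Float64" '
                 'NumberOfComponents="3" format="ascii">\n')
        for p in pts:
            fh.write(f"          {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write("        </DataArray>\n      </Points>\n")
        fh.write('      <PointData Scalars="radius">\n        <DataArray '
                 'type="Float64" Name="radius" format="ascii">\n')
        fh.write("          " + " ".join(f"{r:.6f}" for r in rad) + "\n")
        fh.write("        </DataArray>\n      </PointData>\n")
        fh.write("      <Lines>\n")
        fh.write('        <DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write("          " + " ".join(str(i) for i in connectivity) + "\n")
        fh.write("        </DataArray>\n")
        fh.write('        <DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write("          " + " ".join(str(o) for o in offsets) + "\n")
        fh.write("        </DataArray>\n      </Lines>\n")
        fh.write("    </Piece>\n  </PolyData>\n</VTKFile>\n")
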