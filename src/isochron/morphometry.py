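"""Dendrite-centric measurements.

Cable length, random 10 µm fragment sampling, spine/shaft/filopodia
densities per µm, fragment diameters, spine-to-shaft distances, and the
single-section (2D) bulk density estimate with its ≥5-vesicle inclusion
rule.  All densities are ``count / actual path length``; tip-truncated
fragments keep their true (shorter) length as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import (
    DENDRITIC,
    Compartment,
    Dataset,
    Skeleton,
    SynapseAnnotation,
    TargetClass,
)
from .stats import mean_sem

__all__ = [
    "DendriteFragment",
    "DensityRecord",
    "cable_length",
    "sample_fragments",
    "whole_dendrite_fragment",
    "fragment_density",
    "filopodia_density",
    "fragment_diameter",
    "spine_branch_distance",
    "bulk_2d_density",
    "BulkDensityResult",
]


@dataclass
class DendriteFragment:
    """A connected path of skeleton nodes traced for ~10 µm."""

    skeleton_id: str
    node_path: list[int]
    path_length: float  # µm
    diameter: float  # µm, 2 × mean node radius
    compartment: Compartment
    truncated: bool = False  # hit a tip before reaching the target length


@dataclass
class DensityRecord:
    skeleton_id: str
    path_length: float
    spine_count: int = 0
    shaft_count: int = 0
    filopodia_count: int = 0
    truncated: bool = False

    @property
    def spine_density(self) -> float:
        return self.spine_count / self.path_length

    @property
    def shaft_density(self) -> float:
        return self.shaft_count / self.path_length

    @property
    def filopodia_density(self) -> float:
        return self.filopodia_count / self.path_length


def cable_length(skeleton: Skeleton, node_subset: set[int] | None = None) -> float:
    """Summed Euclidean edge length over the skeleton (or a connected subset).

    A disconnected subset raises: cable length is only meaningful along a
    connected piece of the tree.
    """
    if node_subset is None:
        return skeleton.cable_length()
    subset = set(node_subset)
    missing = subset - set(skeleton.nodes)
    if missing:
        raise ValueError(f"nodes not in skeleton: {sorted(missing)}")
    g = skeleton.graph().subgraph(subset)
    import networkx as nx

    if len(subset) > 1 and not nx.is_connected(g):
        raise ValueError("node subset is not connected")
    total = 0.0
    for nid in subset:
        pid = skeleton.nodes[nid].parent_id
        if pid is not None and pid in subset:
            total += skeleton.edge_length(nid)
    return total


def sample_fragments(
    skeleton: Skeleton,
    target_length: float = 10.0,
    n: int = 20,
    seed: int = 0,
    rule: str = "traverse_branch",
) -> list[DendriteFragment]:
    """Sample ``n`` random dendrite fragments of ~``target_length`` µm.

    A start node is drawn at random (without replacement) from the dendritic
    nodes; the path is extended toward the tips.  At a branch point the
    ``traverse_branch`` rule continues into the thicker daughter, while
    ``stop_at_branch`` ends the fragment there.  Fragments that hit a tip
    short of the target keep their true length and carry a truncation flag.
    """
    if rule not in ("traverse_branch", "stop_at_branch"):
        raise ValueError(f"unknown rule {rule!r}")
    dn = skeleton.node_ids_of(DENDRITIC)
    if not dn:
        raise ValueError(f"skeleton {skeleton.skeleton_id} has no dendritic cable")
    rng = np.random.default_rng(seed)
    starts = rng.choice(dn, size=min(n, len(dn)), replace=False)
    children = skeleton.children()
    frags = []
    for start in sorted(int(s) for s in starts):
        path = [start]
        length = 0.0
        truncated = False
        cur = start
        while length < target_length - 1e-9:
            kids = [k for k in children[cur]
                    if skeleton.nodes[k].compartment in DENDRITIC]
            if not kids:
                truncated = True
                break
            if len(kids) > 1:
                if rule == "stop_at_branch":
                    truncated = True
                    break
                kids = [max(kids, key=lambda k: skeleton.nodes[k].radius)]
            nxt = kids[0]
            length += skeleton.edge_length(nxt)
            path.append(nxt)
            cur = nxt
        radii = [skeleton.nodes[nid].radius for nid in path]
        frags.append(DendriteFragment(
            skeleton_id=skeleton.skeleton_id,
            node_path=path,
            path_length=length,
            diameter=2.0 * float(np.mean(radii)),
            compartment=skeleton.nodes[start].compartment,
            truncated=truncated,
        ))
    return frags


def whole_dendrite_fragment(skeleton: Skeleton) -> DendriteFragment:
    """The root-to-tip path of a dendrite as one fragment.

    Follows the thicker daughter at branch points; on the unbranched
    polylines the generators produce this covers the entire cable.
    """
    dn = set(skeleton.node_ids_of(DENDRITIC))
    if not dn:
        raise ValueError(f"skeleton {skeleton.skeleton_id} has no dendritic cable")
    children = skeleton.children()
    cur = skeleton.root_id
    if cur not in dn:  # descend to the first dendritic node
        while cur not in dn:
            kids = [k for k in children[cur]]
            if not kids:
                raise ValueError("no dendritic path from root")
            cur = max(kids, key=lambda k: skeleton.nodes[k].radius)
    path = [cur]
    length = 0.0
    while True:
        kids = [k for k in children[cur] if k in dn]
        if not kids:
            break
        cur = max(kids, key=lambda k: skeleton.nodes[k].radius)
        length += skeleton.edge_length(cur)
        path.append(cur)
    radii = [skeleton.nodes[nid].radius for nid in path]
    return DendriteFragment(
        skeleton_id=skeleton.skeleton_id, node_path=path, path_length=length,
        diameter=2.0 * float(np.mean(radii)),
        compartment=skeleton.nodes[path[0]].compartment, truncated=False,
    )


def fragment_density(
    fragment: DendriteFragment,
    dataset: Dataset,
    annotation_class: str | None = None,
) -> DensityRecord | float:
    """Count annotations assigned to the fragment's nodes, per µm of path.

    Membership is by the annotation's ``post_node_id`` (annotator assignment),
    not spatial proximity.  With ``annotation_class`` in
    ``{"spine", "shaft", "filopodia"}`` the matching scalar density is
    returned; otherwise the full :class:`DensityRecord`.
    """
    if fragment.path_length <= 0:
        raise ValueError("fragment has zero path length")
    sk = dataset.skeleton(fragment.skeleton_id)
    nodes = set(fragment.node_path)
    rec = DensityRecord(fragment.skeleton_id, fragment.path_length,
                        truncated=fragment.truncated)
    for s in dataset.synapses:
        if s.post_cell_id == sk.cell_id and s.post_node_id in nodes:
            if s.target_class == TargetClass.SPINE:
                rec.spine_count += 1
            elif s.target_class == TargetClass.SHAFT:
                rec.shaft_count += 1
    for f in dataset.filopodia:
        if f.post_cell_id == sk.cell_id and f.base_node_id in nodes:
            rec.filopodia_count += 1
    if annotation_class is None:
        return rec
    try:
        return {"spine": rec.spine_density,
                "shaft": rec.shaft_density,
                "filopodia": rec.filopodia_density}[annotation_class]
    except KeyError:
        raise ValueError(f"unknown annotation_class {annotation_class!r}") from None


def filopodia_density(fragment: DendriteFragment, dataset: Dataset) -> float:
    """Filopodia per µm on the fragment path."""
    return fragment_density(fragment, dataset, "filopodia")


def fragment_diameter(fragment: DendriteFragment) -> float:
    """Fragment diameter: 2 × mean node radius along the path.

    Skeletons carry one radius per node, so this replaces the three-view
    image measurement with its skeleton-native proxy (spines excluded; the
    radius describes the shaft).
    """
    return fragment.diameter


def spine_branch_distance(synapse: SynapseAnnotation, skeleton: Skeleton) -> float:
    """Distance (nm) from a spine synapse to the nearest dendritic cable point."""
    if synapse.target_class != TargetClass.SPINE:
        raise ValueError(
            f"synapse {synapse.synapse_id} targets {synapse.target_class.value}, not a spine"
        )
    p = synapse.position
    best = np.inf
    for node in skeleton.nodes.values():
        if node.compartment not in DENDRITIC:
            continue
        if node.parent_id is None:
            best = min(best, float(np.linalg.norm(p - node.position)))
            continue
        a = skeleton.nodes[node.parent_id].position
        b = node.position
        ab = b - a
        denom = float(ab.dot(ab))
        t = 0.0 if denom == 0 else float(np.clip((p - a).dot(ab) / denom, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    if not np.isfinite(best):
        raise ValueError(f"skeleton {skeleton.skeleton_id} has no dendritic cable")
    return best * 1000.0  # µm -> nm


@dataclass
class BulkDensityResult:
    per_fov: np.ndarray  # qualifying synapses / µm², one entry per FOV
    mean: float
    sem: float


def bulk_2d_density(
    fov_counts: pd.DataFrame,
    fov_area_um2: float,
    min_vesicles: int = 5,
    n_fov: int | None = None,
) -> BulkDensityResult:
    """Single-section synapse density per FOV, excluding sparse-vesicle profiles.

    ``fov_counts`` has one row per detected profile (``fov_id``,
    ``vesicle_count``); only detections with at least ``min_vesicles``
    vesicles qualify.  FOVs with no rows count as zero, so pass ``n_fov``
    (or provide it via ``fov_counts.attrs``) when some FOVs are empty.
    """
    if not fov_area_um2 > 0:
        raise ValueError("fov_area_um2 must be > 0")
    if n_fov is None:
        n_fov = fov_counts.attrs.get("n_fov")
    if n_fov is None:
        n_fov = int(fov_counts["fov_id"].max()) + 1 if len(fov_counts) else 1
    counts = np.zeros(n_fov)
    if len(fov_counts):
        qual = fov_counts[fov_counts["vesicle_count"] >= min_vesicles]
        got = qual.groupby("fov_id").size()
        for fid, c in got.items():
            counts[int(fid)] = c
    dens = counts / fov_area_um2
    m, s = mean_sem(dens)
    return BulkDensityResult(per_fov=dens, mean=m, sem=s)
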