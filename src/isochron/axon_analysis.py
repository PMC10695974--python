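"""Axon-centric measurements.

Per-axon synapse and branch frequencies, the operational excitatory-axon
classification (trace from a seed bouton until three further synapses are
seen; any spine target licenses the excitatory call), the composition of
shaft inputs, and retraction-bulb detection (a terminal swelling packed
with mitochondria, the anatomical signature of branch-specific pruning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Compartment, Dataset, Skeleton, SynapseAnnotation, TargetClass

__all__ = [
    "AxonTraceStats",
    "axon_trace_stats",
    "AxonClassification",
    "classify_axon",
    "shaft_input_composition",
    "detect_retraction_bulbs",
]


@dataclass
class AxonTraceStats:
    axon_id: str
    cable_length: float  # µm
    synapse_count: int
    branch_count: int
    bulb_terminals: list[int] = field(default_factory=list)

    @property
    def synapses_per_um(self) -> float:
        return self.synapse_count / self.cable_length

    @property
    def branches_per_um(self) -> float:
        return self.branch_count / self.cable_length


def axon_trace_stats(axon: Skeleton, dataset: Dataset) -> AxonTraceStats:
    """Synapse and branch frequency of one traced axon.

    Branch points are nodes with ≥ 2 children; synapses are the dataset
    entries whose presynaptic axon is this skeleton's cell.
    """
    length = axon.cable_length()
    if length <= 0:
        raise ValueError(f"axon {axon.skeleton_id} has zero cable length")
    children = axon.children()
    branches = sum(1 for kids in children.values() if len(kids) >= 2)
    n_syn = sum(1 for s in dataset.synapses if s.pre_axon_id == axon.cell_id)
    return AxonTraceStats(axon_id=axon.cell_id, cable_length=length,
                          synapse_count=n_syn, branch_count=branches)


@dataclass
class AxonClassification:
    label: str  # excitatory | unclassified
    n_additional: int
    insufficient: bool  # fewer additional synapses than required


def _path_distances_from(axon: Skeleton, start: int) -> dict[int, float]:
    """Path distance (µm) from ``start`` to every node, along the tree."""
    adj: dict[int, list[tuple[int, float]]] = {nid: [] for nid in axon.nodes}
    for nid in axon.nodes:
        pid = axon.nodes[nid].parent_id
        if pid is not None:
            w = axon.edge_length(nid)
            adj[nid].append((pid, w))
            adj[pid].append((nid, w))
    dist = {start: 0.0}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nxt, w in adj[cur]:
            if nxt not in dist:
                dist[nxt] = dist[cur] + w
                stack.append(nxt)
    return dist


def _nearest_node(axon: Skeleton, position: np.ndarray) -> int:
    ids = sorted(axon.nodes)
    pts = np.array([axon.nodes[nid].position for nid in ids])
    return ids[int(np.argmin(np.linalg.norm(pts - position, axis=1)))]


def classify_axon(
    axon: Skeleton,
    dataset: Dataset,
    seed_synapse: SynapseAnnotation | None = None,
    min_additional: int = 3,
) -> AxonClassification:
    """Excitatory-or-unclassified call from the first few traced synapses.

    Starting at the seed bouton, the axon's other synapses are visited in
    path order (distance along the cable from the seed).  If any of the
    first ``min_additional`` targets a spine the axon is excitatory;
    otherwise it stays unclassified — the rule only ever licenses the
    excitatory call.  With fewer than ``min_additional`` synapses available
    the axon is unclassified with an insufficiency flag.
    """
    own = [s for s in dataset.synapses if s.pre_axon_id == axon.cell_id]
    if seed_synapse is not None:
        own = [s for s in own if s.synapse_id != seed_synapse.synapse_id]
        start = _nearest_node(axon, seed_synapse.position)
    else:
        start = axon.root_id
    dist = _path_distances_from(axon, start)
    own.sort(key=lambda s: (dist.get(_nearest_node(axon, s.position), np.inf),
                            s.synapse_id))
    considered = own[:min_additional]
    if len(own) < min_additional:
        return AxonClassification("unclassified", len(own), insufficient=True)
    if any(s.target_class == TargetClass.SPINE for s in considered):
        return AxonClassification("excitatory", len(considered), insufficient=False)
    return AxonClassification("unclassified", len(considered), insufficient=False)


def shaft_input_composition(
    dataset: Dataset,
    n_sample: int = 30,
    seed: int = 0,
    min_additional: int = 3,
) -> float:
    """Fraction of sampled shaft boutons whose axon classifies as excitatory.

    Samples ``n_sample`` shaft synapses without replacement (only those
    whose presynaptic axon skeleton is present and traceable), classifies
    each axon from its seed bouton, and returns the excitatory fraction
    among the classifiable ones.
    """
    skels = {sk.cell_id for sk in dataset.skeletons}
    from .model_io import CellClass

    excitatory_cells = {sk.cell_id for sk in dataset.skeletons
                        if sk.cell_class == CellClass.EXCITATORY}
    shaft = sorted(
        (s for s in dataset.synapses
         if s.target_class == TargetClass.SHAFT
         and s.post_cell_id in excitatory_cells  # shafts of excitatory dendrites
         and s.pre_axon_id in skels),
        key=lambda s: s.synapse_id,
    )
    if len(shaft) < n_sample:
        raise ValueError(
            f"need at least {n_sample} shaft synapses with traceable axons, "
            f"found {len(shaft)}"
        )
    rng = np.random.default_rng(seed)
    picked = [shaft[i] for i in rng.choice(len(shaft), size=n_sample, replace=False)]
    n_exc = 0
    n_classifiable = 0
    for syn in picked:
        axon = dataset.skeletons_of_cell(syn.pre_axon_id)[0]
        cls = classify_axon(axon, dataset, seed_synapse=syn,
                            min_additional=min_additional)
        if not cls.insufficient:
            n_classifiable += 1
            if cls.label == "excitatory":
                n_exc += 1
    if n_classifiable == 0:
        raise ValueError("no classifiable axons among the sampled shaft boutons")
    return n_exc / n_classifiable


def detect_retraction_bulbs(
    axon: Skeleton,
    dataset: Dataset,
    radius_factor: float = 2.0,
    min_bulb_mitos: int = 3,
    bulb_window_um: float = 2.0,
) -> list[int]:
    """Terminal nodes that look like mitochondria-packed retraction bulbs.

    A terminal (leaf) node is flagged when its radius is at least
    ``radius_factor`` × the median radius of the axon's non-terminal nodes
    AND at least ``min_bulb_mitos`` mitochondria have their span within
    ``bulb_window_um`` (path distance) of that terminal.  Detection is
    branch-specific: other branches of the same axon may carry synapses.
    """
    children = axon.children()
    leaves = [nid for nid, kids in children.items()
              if not kids and axon.nodes[nid].parent_id is not None]
    non_terminal = [axon.nodes[nid].radius for nid in axon.nodes if nid not in set(leaves)]
    if not non_terminal:
        return []
    med = float(np.median(non_terminal))
    mitos = [m for m in dataset.mitochondria if m.host_skeleton_id == axon.skeleton_id]
    out = []
    for leaf in sorted(leaves):
        if axon.nodes[leaf].radius < radius_factor * med:
            continue
        dist = _path_distances_from(axon, leaf)
        n_close = sum(
            1 for m in mitos
            if dist.get(m.start_node_id, np.inf) <= bulb_window_um
            and dist.get(m.end_node_id, np.inf) <= bulb_window_um
        )
        if n_close >= min_bulb_mitos:
            out.append(leaf)
    return out
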