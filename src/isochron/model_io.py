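"""Domain types and file I/O for skeletonized EM reconstructions.

The package works on three kinds of objects:

* :class:`Skeleton` — a rooted tree of 3D nodes (positions and radii in µm)
  with per-node compartment labels, read from / written to standard
  seven-column SWC.
* annotation records — :class:`SynapseAnnotation`,
  :class:`FilopodiumAnnotation` and :class:`MitochondrionInstance`, stored as
  plain CSV tables whose columns are named after the dataclass fields.
* :class:`Dataset` — a bundle of skeletons plus annotations plus metadata,
  persisted as a directory ``{skeletons.swc, synapses.csv, filopodia.csv,
  mitochondria.csv, metadata.json}``.

Units are fixed package-wide: coordinates and radii in µm, PSD areas in nm²,
mitochondrion volumes in nm³.  These match how the measured quantities are
conventionally printed and avoid silent unit drift between analyses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Compartment",
    "CellClass",
    "TargetClass",
    "SkeletonNode",
    "Skeleton",
    "SynapseAnnotation",
    "FilopodiumAnnotation",
    "MitochondrionInstance",
    "Dataset",
    "ValidationError",
    "ValidationReport",
    "DEFAULT_SWC_TYPE_MAP",
    "read_swc",
    "write_swc",
    "read_annotations",
    "write_annotations",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]


class Compartment(str, Enum):
    SOMA = "soma"
    AXON = "axon"
    DENDRITE_BASAL = "dendrite_basal"
    DENDRITE_APICAL = "dendrite_apical"
    FILOPODIUM = "filopodium"


#: Compartments counted as dendritic cable for density denominators.
DENDRITIC = frozenset({Compartment.DENDRITE_BASAL, Compartment.DENDRITE_APICAL})


class CellClass(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    UNCLASSIFIED = "unclassified"


class TargetClass(str, Enum):
    SPINE = "spine"
    SHAFT = "shaft"
    SOMA = "soma"


#: SWC integer type code → compartment.  Codes 1/2/3/4 follow the common SWC
#: convention (soma/axon/basal/apical); code 5 is repurposed for filopodia.
DEFAULT_SWC_TYPE_MAP: dict[int, Compartment] = {
    1: Compartment.SOMA,
    2: Compartment.AXON,
    3: Compartment.DENDRITE_BASAL,
    4: Compartment.DENDRITE_APICAL,
    5: Compartment.FILOPODIUM,
}

_SWC_CODE_FOR = {v: k for k, v in DEFAULT_SWC_TYPE_MAP.items()}


class ValidationError(ValueError):
    """Raised when a skeleton or annotation violates a structural invariant."""


@dataclass
class SkeletonNode:
    node_id: int
    position: np.ndarray  # (3,) µm
    radius: float  # µm
    parent_id: int | None  # None for the root
    compartment: Compartment

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(f"node {self.node_id}: position must be a 3-vector")
        if not self.radius > 0:
            raise ValidationError(f"node {self.node_id}: radius must be > 0, got {self.radius}")


@dataclass
class Skeleton:
    """A rooted tree of nodes; the substrate of all cable-normalized measures."""

    skeleton_id: str
    nodes: dict[int, SkeletonNode]
    cell_id: str = ""
    cell_class: CellClass = CellClass.UNCLASSIFIED
    soma_complete: bool = True

    def __post_init__(self) -> None:
        if not self.cell_id:
            self.cell_id = self.skeleton_id
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        roots = []
        for nid, node in self.nodes.items():
            if nid != node.node_id:
                raise ValidationError(f"node {nid}: key does not match node_id {node.node_id}")
            if node.parent_id is None:
                roots.append(nid)
            elif node.parent_id not in self.nodes:
                raise ValidationError(
                    f"node {node.node_id}: dangling parent {node.parent_id}"
                )
        if self.nodes and len(roots) != 1:
            raise ValidationError(
                f"skeleton {self.skeleton_id}: expected exactly one root, found {len(roots)}"
            )
        # cycle check: walk each node to the root, memoizing verified nodes
        verified: set[int] = set()
        for nid in self.nodes:
            seen: set[int] = set()
            cur: int | None = nid
            while cur is not None and cur not in verified:
                if cur in seen:
                    raise ValidationError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
            verified |= seen

    @property
    def root_id(self) -> int:
        for nid, node in self.nodes.items():
            if node.parent_id is None:
                return nid
        raise ValidationError(f"skeleton {self.skeleton_id} has no root")

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                out[node.parent_id].append(node.node_id)
        for kids in out.values():
            kids.sort()
        return out

    def edge_length(self, node_id: int) -> float:
        """Length of the edge from ``node_id`` to its parent (0 for the root)."""
        node = self.nodes[node_id]
        if node.parent_id is None:
            return 0.0
        return float(np.linalg.norm(node.position - self.nodes[node.parent_id].position))

    def cable_length(self) -> float:
        return float(sum(self.edge_length(nid) for nid in self.nodes))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (n.node_id, n.parent_id) for n in self.nodes.values() if n.parent_id is not None
        )
        return g

    def node_ids_of(self, compartments: Iterable[Compartment]) -> list[int]:
        wanted = set(compartments)
        return sorted(n.node_id for n in self.nodes.values() if n.compartment in wanted)


@dataclass
class SynapseAnnotation:
    """One synaptic contact: a presynaptic bouton apposed to a PSD-bearing target."""

    synapse_id: str
    pre_axon_id: str
    post_cell_id: str
    post_node_id: int
    target_class: TargetClass
    position: np.ndarray  # (3,) µm
    psd_area: float | None = None  # nm²
    vesicle_count: int | None = None
    bouton_radius: float | None = None  # µm
    vesicle_cloud_size: float | None = None  # nm³
    pre_excitatory: bool | None = None  # generator ground truth, when known

    def __post_init__(self) -> None:
        # range checks live in validate_dataset, which reports rather than raises
        self.position = np.asarray(self.position, dtype=float)
        self.target_class = TargetClass(self.target_class)


@dataclass
class FilopodiumAnnotation:
    """A long dendritic protrusion with no postsynaptic structure."""

    filopodium_id: str
    post_cell_id: str
    base_node_id: int
    length: float  # µm


@dataclass
class MitochondrionInstance:
    mito_id: str
    host_skeleton_id: str
    volume: float  # nm³
    start_node_id: int
    end_node_id: int


@dataclass
class Dataset:
    """Skeletons plus annotations plus provenance metadata."""

    skeletons: list[Skeleton] = field(default_factory=list)
    synapses: list[SynapseAnnotation] = field(default_factory=list)
    filopodia: list[FilopodiumAnnotation] = field(default_factory=list)
    mitochondria: list[MitochondrionInstance] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def skeleton(self, skeleton_id: str) -> Skeleton:
        for sk in self.skeletons:
            if sk.skeleton_id == skeleton_id:
                return sk
        raise KeyError(f"no skeleton {skeleton_id!r} in dataset")

    def skeletons_of_cell(self, cell_id: str) -> list[Skeleton]:
        return [sk for sk in self.skeletons if sk.cell_id == cell_id]

    def synapses_onto(self, cell_id: str) -> list[SynapseAnnotation]:
        return [s for s in self.synapses if s.post_cell_id == cell_id]

    def synapses_from_axon(self, axon_id: str) -> list[SynapseAnnotation]:
        return [s for s in self.synapses if s.pre_axon_id == axon_id]


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(
    path: str | Path,
    compartment_map: Mapping[int, Compartment] | None = None,
    default_compartment: Compartment = Compartment.DENDRITE_BASAL,
) -> list[Skeleton]:
    """Read an SWC file; one :class:`Skeleton` per connected component.

    Unknown type codes map to ``default_compartment`` with a logged warning.
    A dangling parent or a non-positive radius raises :class:`ValidationError`
    naming the offending node.
    """
    cmap = dict(DEFAULT_SWC_TYPE_MAP if compartment_map is None else compartment_map)
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValidationError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        nid, tcode = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        rows.append((nid, tcode, x, y, z, r, parent))

    all_ids = {r[0] for r in rows}
    if len(all_ids) != len(rows):
        raise ValidationError(f"{path}: duplicate node ids")
    nodes: dict[int, SkeletonNode] = {}
    for nid, tcode, x, y, z, r, parent in rows:
        if parent != -1 and parent not in all_ids:
            raise ValidationError(f"node {nid}: dangling parent {parent}")
        if tcode not in cmap:
            logger.warning("node %d: unknown SWC type code %d, using %s", nid, tcode, default_compartment.value)
        comp = cmap.get(tcode, default_compartment)
        if not r > 0:
            raise ValidationError(f"node {nid}: radius must be > 0, got {r}")
        nodes[nid] = SkeletonNode(nid, np.array([x, y, z]), r, None if parent == -1 else parent, comp)

    # split into connected components, stable by smallest node id
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((nid, n.parent_id) for nid, n in nodes.items() if n.parent_id is not None)
    skeletons = []
    for idx, comp_ids in enumerate(sorted(nx.connected_components(g), key=min)):
        sk_nodes = {nid: nodes[nid] for nid in sorted(comp_ids)}
        skeletons.append(Skeleton(skeleton_id=f"swc{idx:04d}", nodes=sk_nodes))
    return skeletons


def write_swc(skeletons: Sequence[Skeleton], path: str | Path) -> None:
    """Write skeletons to one SWC file, one line per node, ordered by node_id.

    Node ids must be unique across the whole collection (a collision raises).
    """
    seen: dict[int, str] = {}
    lines = ["# SWC export: id type x y z radius parent"]
    all_nodes: list[SkeletonNode] = []
    for sk in skeletons:
        for node in sk.nodes.values():
            if node.node_id in seen:
                raise ValidationError(
                    f"node id {node.node_id} appears in both {seen[node.node_id]!r} "
                    f"and {sk.skeleton_id!r}"
                )
            seen[node.node_id] = sk.skeleton_id
            all_nodes.append(node)
    for node in sorted(all_nodes, key=lambda n: n.node_id):
        x, y, z = node.position
        parent = -1 if node.parent_id is None else node.parent_id
        lines.append(
            f"{node.node_id} {_SWC_CODE_FOR[node.compartment]} "
            f"{x:.6f} {y:.6f} {z:.6f} {node.radius:.6f} {parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation CSVs
# ---------------------------------------------------------------------------

_SYN_COLS = [
    "synapse_id", "pre_axon_id", "post_cell_id", "post_node_id", "target_class",
    "x", "y", "z", "psd_area", "vesicle_count", "bouton_radius",
    "vesicle_cloud_size", "pre_excitatory",
]
_FILO_COLS = ["filopodium_id", "post_cell_id", "base_node_id", "length"]
_MITO_COLS = ["mito_id", "host_skeleton_id", "volume", "start_node_id", "end_node_id"]


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def _opt_int(v) -> int | None:
    return None if pd.isna(v) else int(v)


def read_annotations(
    synapse_csv: str | Path | None = None,
    filopodia_csv: str | Path | None = None,
    mito_csv: str | Path | None = None,
) -> Dataset:
    """Read annotation CSVs into a (skeleton-less) :class:`Dataset`.

    Optional columns may be absent from the file and yield ``None`` fields.
    An unknown ``target_class`` string raises, listing the permitted values.
    """
    ds = Dataset()
    if synapse_csv is not None:
        df = pd.read_csv(synapse_csv, float_precision="round_trip")
        permitted = {t.value for t in TargetClass}
        bad = set(df["target_class"].astype(str)) - permitted if len(df) else set()
        if bad:
            raise ValidationError(
                f"unknown target_class value(s) {sorted(bad)}; permitted: {sorted(permitted)}"
            )
        for row in df.itertuples(index=False):
            d = row._asdict()
            ds.synapses.append(
                SynapseAnnotation(
                    synapse_id=str(d["synapse_id"]),
                    pre_axon_id=str(d["pre_axon_id"]),
                    post_cell_id=str(d["post_cell_id"]),
                    post_node_id=int(d["post_node_id"]),
                    target_class=TargetClass(d["target_class"]),
                    position=np.array([d["x"], d["y"], d["z"]], dtype=float),
                    psd_area=_opt_float(d.get("psd_area")),
                    vesicle_count=_opt_int(d.get("vesicle_count")),
                    bouton_radius=_opt_float(d.get("bouton_radius")),
                    vesicle_cloud_size=_opt_float(d.get("vesicle_cloud_size")),
                    pre_excitatory=(None if pd.isna(d.get("pre_excitatory", float("nan")))
                                    else bool(d["pre_excitatory"])),
                )
            )
    if filopodia_csv is not None:
        for row in pd.read_csv(filopodia_csv, float_precision="round_trip").itertuples(index=False):
            d = row._asdict()
            ds.filopodia.append(
                FilopodiumAnnotation(str(d["filopodium_id"]), str(d["post_cell_id"]),
                                     int(d["base_node_id"]), float(d["length"]))
            )
    if mito_csv is not None:
        for row in pd.read_csv(mito_csv, float_precision="round_trip").itertuples(index=False):
            d = row._asdict()
            ds.mitochondria.append(
                MitochondrionInstance(str(d["mito_id"]), str(d["host_skeleton_id"]),
                                      float(d["volume"]), int(d["start_node_id"]),
                                      int(d["end_node_id"]))
            )
    return ds


def write_annotations(ds: Dataset, synapse_csv: Path, filopodia_csv: Path, mito_csv: Path) -> None:
    syn_rows = []
    for s in ds.synapses:
        x, y, z = s.position
        syn_rows.append({
            "synapse_id": s.synapse_id, "pre_axon_id": s.pre_axon_id,
            "post_cell_id": s.post_cell_id, "post_node_id": s.post_node_id,
            "target_class": s.target_class.value, "x": x, "y": y, "z": z,
            "psd_area": s.psd_area, "vesicle_count": s.vesicle_count,
            "bouton_radius": s.bouton_radius, "vesicle_cloud_size": s.vesicle_cloud_size,
            "pre_excitatory": s.pre_excitatory,
        })
    pd.DataFrame(syn_rows, columns=_SYN_COLS).to_csv(synapse_csv, index=False)
    pd.DataFrame(
        [{"filopodium_id": f.filopodium_id, "post_cell_id": f.post_cell_id,
          "base_node_id": f.base_node_id, "length": f.length} for f in ds.filopodia],
        columns=_FILO_COLS,
    ).to_csv(filopodia_csv, index=False)
    pd.DataFrame(
        [{"mito_id": m.mito_id, "host_skeleton_id": m.host_skeleton_id, "volume": m.volume,
          "start_node_id": m.start_node_id, "end_node_id": m.end_node_id}
         for m in ds.mitochondria],
        columns=_MITO_COLS,
    ).to_csv(mito_csv, index=False)


# ---------------------------------------------------------------------------
# Dataset bundle directory
# ---------------------------------------------------------------------------

def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Persist a dataset as ``{skeletons.swc, *.csv, metadata.json}``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_swc(ds.skeletons, out / "skeletons.swc")
    write_annotations(ds, out / "synapses.csv", out / "filopodia.csv", out / "mitochondria.csv")
    meta = dict(ds.metadata)
    meta["skeletons"] = {
        str(sk.root_id): {
            "skeleton_id": sk.skeleton_id,
            "cell_id": sk.cell_id,
            "cell_class": sk.cell_class.value,
            "soma_complete": sk.soma_complete,
        }
        for sk in ds.skeletons
        if sk.nodes
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return out


def read_dataset(in_dir: str | Path) -> Dataset:
    src = Path(in_dir)
    skeletons = read_swc(src / "skeletons.swc")
    meta = json.loads((src / "metadata.json").read_text())
    sk_meta = meta.pop("skeletons", {})
    for sk in skeletons:
        info = sk_meta.get(str(sk.root_id))
        if info:
            sk.skeleton_id = info["skeleton_id"]
            sk.cell_id = info["cell_id"]
            sk.cell_class = CellClass(info["cell_class"])
            sk.soma_complete = bool(info["soma_complete"])
    ds = read_annotations(src / "synapses.csv", src / "filopodia.csv", src / "mitochondria.csv")
    ds.skeletons = skeletons
    ds.metadata = meta
    return ds


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __len__(self) -> int:
        return len(self.findings)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report (do not raise) unresolved references and out-of-range values."""
    rep = ValidationReport()
    cells: dict[str, set[int]] = {}
    skels: dict[str, set[int]] = {}
    for sk in ds.skeletons:
        cells.setdefault(sk.cell_id, set()).update(sk.nodes)
        skels[sk.skeleton_id] = set(sk.nodes)
    for s in ds.synapses:
        if s.psd_area is not None and not s.psd_area > 0:
            rep.findings.append(f"synapse {s.synapse_id}: non-positive psd_area")
        if s.bouton_radius is not None and not s.bouton_radius > 0:
            rep.findings.append(f"synapse {s.synapse_id}: non-positive bouton_radius")
        if s.vesicle_count is not None and s.vesicle_count < 0:
            rep.findings.append(f"synapse {s.synapse_id}: negative vesicle_count")
        if s.post_cell_id not in cells:
            rep.findings.append(f"synapse {s.synapse_id}: unresolved post_cell_id {s.post_cell_id}")
        elif s.post_node_id not in cells[s.post_cell_id]:
            rep.findings.append(
                f"synapse {s.synapse_id}: post_node_id {s.post_node_id} "
                f"not on cell {s.post_cell_id}"
            )
    for f in ds.filopodia:
        if f.post_cell_id not in cells:
            rep.findings.append(f"filopodium {f.filopodium_id}: unresolved post_cell_id {f.post_cell_id}")
        elif f.base_node_id not in cells[f.post_cell_id]:
            rep.findings.append(
                f"filopodium {f.filopodium_id}: base_node_id {f.base_node_id} "
                f"not on cell {f.post_cell_id}"
            )
        if not f.length > 0:
            rep.findings.append(f"filopodium {f.filopodium_id}: non-positive length")
    for m in ds.mitochondria:
        if m.host_skeleton_id not in skels:
            rep.findings.append(f"mitochondrion {m.mito_id}: unresolved host {m.host_skeleton_id}")
        else:
            span_ok = m.start_node_id in skels[m.host_skeleton_id] and m.end_node_id in skels[m.host_skeleton_id]
            if not span_ok:
                rep.findings.append(
                    f"mitochondrion {m.mito_id}: span ({m.start_node_id}, {m.end_node_id}) "
                    f"not on host {m.host_skeleton_id}"
                )
        if not m.volume > 0:
            rep.findings.append(f"mitochondrion {m.mito_id}: non-positive volume")
    return rep
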