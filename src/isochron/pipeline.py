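"""Pipeline orchestration: simulate → measure → compare → report.

A :class:`RunConfig` (YAML/JSON-loadable) lists the datasets to simulate,
the measurement parameters, and the pairwise comparisons to run.  The run
writes, under one output directory:

* ``datasets/<name>/`` — the simulated dataset bundles;
* ``measurements/<name>.<kind>.csv`` — fragment densities, soma profiles,
  axon stats, mitochondria records;
* ``comparisons/<a>__vs__<b>.<metric>.json`` — Mann-Whitney results with
  figure-style significance annotations;
* ``summary.csv`` — the age-series table (mean ± sem per dataset/metric);
* ``manifest.json`` — seeds, parameters and versions; rerunning with the
  same config reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .axon_analysis import axon_trace_stats, detect_retraction_bulbs
from .innervation import soma_profile
from .model_io import (
    CellClass,
    Compartment,
    DENDRITIC,
    Dataset,
    write_dataset,
)
from .morphometry import fragment_density, sample_fragments
from .organelles import coverage_synapse_correlation, mito_dendrite_record
from .profiles import load_profile
from .stats import mann_whitney_u, mean_sem, significance_stars
from .synthetic import simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSpec",
    "RunConfig",
    "run_pipeline",
    "measure_dendrites",
    "measure_somata",
    "measure_axons",
    "measure_mitochondria",
    "METRIC_SOURCES",
]


@dataclass
class DatasetSpec:
    profile: str
    n_dendrites: int = 20
    n_somata: int = 8
    n_axons: int = 30
    seed: int = 0


@dataclass
class RunConfig:
    datasets: list[DatasetSpec]
    comparisons: list[dict] = field(default_factory=list)  # {a, b, metric}
    fragment_length_um: float = 10.0
    n_fragments: int = 20
    fragment_rule: str = "traverse_branch"
    measure_seed: int = 0
    out_dir: str = "isochron_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["datasets"] = [DatasetSpec(**ds) for ds in d.get("datasets", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


# metric name -> (measurement kind, column)
METRIC_SOURCES: dict[str, tuple[str, str]] = {
    "spine_density": ("dendrites", "spine_density"),
    "shaft_density": ("dendrites", "shaft_density"),
    "filopodia_density": ("dendrites", "filopodia_density"),
    "diameter": ("dendrites", "diameter"),
    "soma_synapses": ("somata", "total_soma_synapses"),
    "axons_per_soma": ("somata", "innervating_axons"),
    "axon_synapses_per_um": ("axons", "synapses_per_um"),
    "axon_branches_per_um": ("axons", "branches_per_um"),
    "mito_density": ("mitochondria", "mito_density"),
    "mean_mito_size": ("mitochondria", "mean_mito_size"),
}


def _primary_dendrites(ds: Dataset):
    return [sk for sk in ds.skeletons
            if sk.cell_class == CellClass.EXCITATORY
            and any(n.compartment in DENDRITIC for n in sk.nodes.values())]


def measure_dendrites(
    ds: Dataset,
    n_fragments: int = 20,
    fragment_length_um: float = 10.0,
    seed: int = 0,
    rule: str = "traverse_branch",
) -> pd.DataFrame:
    """Random-fragment density table: one row per 10 µm dendrite fragment."""
    dendrites = _primary_dendrites(ds)
    if not dendrites:
        raise ValueError("dataset has no excitatory dendrites to measure")
    per = max(1, -(-n_fragments // len(dendrites)))  # ceil division
    rows = []
    for i, sk in enumerate(dendrites):
        for frag in sample_fragments(sk, fragment_length_um, per, seed=seed + i, rule=rule):
            rec = fragment_density(frag, ds)
            if frag.truncated:
                logger.warning("fragment on %s truncated at %.2f µm",
                               sk.skeleton_id, frag.path_length)
            rows.append({
                "skeleton_id": sk.skeleton_id,
                "compartment": frag.compartment.value,
                "path_length": frag.path_length,
                "truncated": frag.truncated,
                "diameter": frag.diameter,
                "spine_count": rec.spine_count,
                "shaft_count": rec.shaft_count,
                "filopodia_count": rec.filopodia_count,
                "spine_density": rec.spine_density,
                "shaft_density": rec.shaft_density,
                "filopodia_density": rec.filopodia_density,
            })
    return pd.DataFrame(rows[: max(n_fragments, 1)] if len(rows) > n_fragments else rows)


def measure_somata(ds: Dataset) -> pd.DataFrame:
    rows = []
    for sk in ds.skeletons:
        if sk.cell_class != CellClass.EXCITATORY:
            continue
        if not any(n.compartment == Compartment.SOMA for n in sk.nodes.values()):
            continue
        prof = soma_profile(sk.cell_id, ds)
        rows.append({
            "cell_id": prof.cell_id,
            "total_soma_synapses": prof.total_soma_synapses,
            "innervating_axons": prof.innervating_axons,
            "mean_bouton_volume": prof.mean_bouton_volume,
        })
    return pd.DataFrame(rows)


def measure_axons(ds: Dataset) -> pd.DataFrame:
    rows = []
    for sk in ds.skeletons:
        if sk.cell_class != CellClass.EXCITATORY:
            continue
        nodes = list(sk.nodes.values())
        if not nodes or not all(n.compartment == Compartment.AXON for n in nodes):
            continue
        st = axon_trace_stats(sk, ds)
        bulbs = detect_retraction_bulbs(sk, ds)
        rows.append({
            "axon_id": st.axon_id,
            "cable_length": st.cable_length,
            "synapse_count": st.synapse_count,
            "branch_count": st.branch_count,
            "synapses_per_um": st.synapses_per_um,
            "branches_per_um": st.branches_per_um,
            "n_bulb_terminals": len(bulbs),
        })
    return pd.DataFrame(rows)


def measure_mitochondria(ds: Dataset, compartment: str = "combined") -> pd.DataFrame:
    rows = []
    for sk in _primary_dendrites(ds):
        rec = mito_dendrite_record(sk, ds)
        if compartment == "basal" and rec.compartment != Compartment.DENDRITE_BASAL:
            continue
        if compartment == "apical" and rec.compartment != Compartment.DENDRITE_APICAL:
            continue
        rows.append({
            "skeleton_id": rec.skeleton_id,
            "compartment": rec.compartment.value,
            "cable_length": rec.cable_length,
            "total_mito_volume": rec.total_mito_volume,
            "mito_count": rec.mito_count,
            "mean_mito_size": rec.mean_mito_size,
            "mito_density": rec.mito_density,
            "synapse_density": rec.synapse_density,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full simulate → measure → compare run. Returns the out dir."""
    if not config.datasets:
        raise ValueError("config lists no datasets")
    out = Path(config.out_dir)
    (out / "datasets").mkdir(parents=True, exist_ok=True)
    (out / "measurements").mkdir(exist_ok=True)
    (out / "comparisons").mkdir(exist_ok=True)

    measurements: dict[str, dict[str, pd.DataFrame]] = {}
    ages: dict[str, int] = {}
    for spec in config.datasets:
        profile = load_profile(spec.profile)  # raises listing bundled names
        logger.info("simulating %s (seed %d)", spec.profile, spec.seed)
        ds = simulate_dataset(profile, spec.n_dendrites, spec.n_somata,
                              spec.n_axons, spec.seed)
        write_dataset(ds, out / "datasets" / spec.profile)
        m = {
            "dendrites": measure_dendrites(ds, config.n_fragments,
                                           config.fragment_length_um,
                                           seed=config.measure_seed,
                                           rule=config.fragment_rule),
            "somata": measure_somata(ds),
            "axons": measure_axons(ds),
            "mitochondria": measure_mitochondria(ds),
        }
        for kind, df in m.items():
            df.to_csv(out / "measurements" / f"{spec.profile}.{kind}.csv", index=False)
        measurements[spec.profile] = m
        ages[spec.profile] = profile.age_days

    # comparisons
    for comp in config.comparisons:
        a, b, metric = comp["a"], comp["b"], comp["metric"]
        kind, col = METRIC_SOURCES[metric]
        xa = measurements[a][kind][col].to_numpy()
        xb = measurements[b][kind][col].to_numpy()
        res = mann_whitney_u(xa, xb, labels=(a, b))
        d = res.to_dict()
        d["metric"] = metric
        d["stars"] = significance_stars(res.p_two_tailed)
        path = out / "comparisons" / f"{a}__vs__{b}.{metric}.json"
        path.write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")

    # age-series summary table
    rows = []
    for name, m in measurements.items():
        for metric, (kind, col) in METRIC_SOURCES.items():
            df = m[kind]
            if df.empty or col not in df or df[col].dropna().empty:
                continue
            mu, sem = mean_sem(df[col].dropna().to_numpy())
            rows.append({"dataset": name, "age_days": ages[name],
                         "metric": metric, "mean": mu, "sem": sem,
                         "n": int(df[col].dropna().size)})
    summary = pd.DataFrame(rows).sort_values(["metric", "age_days", "dataset"])
    summary.to_csv(out / "summary.csv", index=False)

    config_echo = config.to_dict()
    config_echo.pop("out_dir", None)  # implicit in the manifest's location
    manifest = {
        "isochron_version": __version__,
        "config": config_echo,
        "datasets": {s.profile: {"seed": s.seed, "age_days": ages[s.profile]}
                     for s in config.datasets},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out
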