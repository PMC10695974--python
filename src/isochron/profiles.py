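"""Age profiles: per-dataset generator parameter sets.

An :class:`AgeProfile` names one (species, region, layer, postnatal day)
condition and carries the mean rates and distribution parameters the
synthetic-data generators draw from: Poisson synapse and filopodia rates per
µm of dendritic cable, somatic innervation means, axonal synapse/branch
frequencies, bouton volume and vesicle-count means, log-normal PSD-area
parameters, and mitochondria coverage targets.

The bundled profiles (``isochron/profiles/*.json``) encode the published
per-age means for mouse and macaque V1 L2/3; quantities that were only
reported qualitatively carry documented defaults (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

__all__ = ["AgeProfile", "load_profile", "bundled_profile_names", "ProfileError"]


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class AgeProfile:
    name: str
    species: str  # mouse | primate
    region: str  # V1 | S1
    layer: str  # L23 | L4
    age_days: int
    spine_rate: float  # spine synapses / µm dendrite
    shaft_rate: float  # shaft synapses / µm dendrite
    filopodia_rate: float  # filopodia / µm dendrite
    soma_synapse_mean: float  # somatic synapses / soma
    axons_per_soma_mean: float  # distinct innervating axons / soma
    axon_synapse_rate: float  # output synapses / µm axon
    axon_branch_rate: float  # branch points / µm axon
    bouton_volume_mean: float  # µm³
    vesicle_count_mean: float  # vesicles / bouton
    psd_logmean: float  # mean of ln(PSD area in nm²)
    psd_logsd: float  # sd of ln(PSD area in nm²)
    mito_density_mean: float  # nm² (nm³ mito volume per nm dendrite)
    mito_synapse_corr: float  # Pearson target, basal dendrites
    excitatory_shaft_fraction: float  # P(shaft synapse comes from an excitatory axon)

    def __post_init__(self) -> None:
        rates = {
            "spine_rate": self.spine_rate,
            "shaft_rate": self.shaft_rate,
            "filopodia_rate": self.filopodia_rate,
            "soma_synapse_mean": self.soma_synapse_mean,
            "axons_per_soma_mean": self.axons_per_soma_mean,
            "axon_synapse_rate": self.axon_synapse_rate,
            "axon_branch_rate": self.axon_branch_rate,
            "bouton_volume_mean": self.bouton_volume_mean,
            "vesicle_count_mean": self.vesicle_count_mean,
            "mito_density_mean": self.mito_density_mean,
        }
        for k, v in rates.items():
            if v < 0:
                raise ProfileError(f"{self.name}: {k} must be >= 0, got {v}")
        if not 0 <= self.excitatory_shaft_fraction <= 1:
            raise ProfileError(f"{self.name}: excitatory_shaft_fraction must be in [0, 1]")
        if not -1 <= self.mito_synapse_corr <= 1:
            raise ProfileError(f"{self.name}: mito_synapse_corr must be in [-1, 1]")
        if self.species not in ("mouse", "primate"):
            raise ProfileError(f"{self.name}: unknown species {self.species!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def bundled_profile_names() -> list[str]:
    files = resources.files("isochron") / "profiles"
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".json"))


def load_profile(name_or_path: str | Path) -> AgeProfile:
    """Load a bundled profile by name, or any profile JSON by path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        data = json.loads(p.read_text())
    else:
        ref = resources.files("isochron") / "profiles" / f"{name_or_path}.json"
        if not ref.is_file():
            raise ProfileError(
                f"unknown profile {name_or_path!r}; bundled profiles: "
                + ", ".join(bundled_profile_names())
            )
        data = json.loads(ref.read_text())
    return AgeProfile(**data)
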