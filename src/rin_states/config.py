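"""Pipeline configuration: a flat, file-round-trippable parameter record."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .landscape import SigmoidParams

#: HDBSCAN parameter presets per embedding method (min_cluster_size,
#: min_samples, cluster_selection_method). The published full-scale analysis
#: used these with a ~300k-frame ensemble; the `synthetic` preset is scaled
#: to the default 2000-frame synthetic ensembles.
HDBSCAN_PRESETS = {
    "pca": {"min_cluster_size": 100, "min_samples": 800,
            "cluster_selection_method": "eom"},
    "encodermap": {"min_cluster_size": 100, "min_samples": 1200,
                   "cluster_selection_method": "leaf"},
    "umap_cd": {"min_cluster_size": 1500, "min_samples": 1500,
                "cluster_selection_method": "eom"},
    "synthetic": {"min_cluster_size": 100, "min_samples": 25,
                  "cluster_selection_method": "eom"},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; serializes losslessly to YAML/JSON."""

    cutoff_angstrom: float = 4.5
    residue_subset: tuple[int, int] | None = None
    embedding_method: str = "pca"           # pca | encodermap-like | umap
    embedding_k: int = 2
    embedding_params: dict = field(default_factory=dict)
    sigmoid_high: SigmoidParams = SigmoidParams(1.1, 6.0, 6.0)
    sigmoid_low: SigmoidParams = SigmoidParams(1.0, 2.0, 6.0)
    min_cluster_size: int = 100
    min_samples: int | None = 25
    cluster_selection_method: str = "eom"
    seed: int = 0
    output_dir: str = "rin_states_out"
    density_bins: int = 200
    difference_threshold: float = 0.5
    n_representatives: int = 10
    closeness_convention: str = "n"

    def __post_init__(self) -> None:
        if self.cutoff_angstrom <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff_angstrom} A")

    @property
    def cutoff_nm(self) -> float:
        return self.cutoff_angstrom * 0.1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigmoid_high"] = list(asdict(self.sigmoid_high).values())
        d["sigmoid_low"] = list(asdict(self.sigmoid_low).values())
        if self.residue_subset is not None:
            d["residue_subset"] = list(self.residue_subset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sigmoid_high") is not None:
            d["sigmoid_high"] = SigmoidParams(*d["sigmoid_high"])
        if d.get("sigmoid_low") is not None:
            d["sigmoid_low"] = SigmoidParams(*d["sigmoid_low"])
        if d.get("residue_subset") is not None:
            d["residue_subset"] = tuple(d["residue_subset"])
        return cls(**d)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    def with_preset(self, name: str) -> "PipelineConfig":
        """Apply a named HDBSCAN parameter preset."""
        p = HDBSCAN_PRESETS[name]
        return replace(self, min_cluster_size=p["min_cluster_size"],
                       min_samples=p["min_samples"],
                       cluster_selection_method=p["cluster_selection_method"])
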