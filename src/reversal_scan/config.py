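"""Pipeline configuration: one plain-text (YAML) file drives every stage.

Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from reversal_scan.harmonize import QCThresholds
from reversal_scan.models import ClassThresholds
from reversal_scan.simulate import SimulationConfig


@dataclass
class InputPaths:
    platform1_pre: str = ""
    platform1_post: str = ""
    platform2_pre: str = ""
    platform2_post: str = ""
    gene_locations: str = ""
    gene_sets: str = ""
    reference_panel: str = ""
    category_map: str = ""


@dataclass
class GeneParams:
    window_bp: int = 0
    mc_draws: int = 100_000
    retain_alpha: float = 0.05


@dataclass
class EnrichParams:
    min_set: int = 3
    max_set: int = 500
    criterion: str = "raw_p"  # or adjusted_p
    alpha: float = 0.05


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    seed: int = 13
    out_dir: str = "results"
    ambiguous_policy: str = "drop"
    inputs: InputPaths = field(default_factory=InputPaths)
    qc: QCThresholds = field(default_factory=QCThresholds)
    classify: ClassThresholds = field(default_factory=ClassThresholds)
    genes: GeneParams = field(default_factory=GeneParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "inputs": InputPaths,
            "qc": QCThresholds,
            "classify": ClassThresholds,
            "genes": GeneParams,
            "enrich": EnrichParams,
            "simulate": SimulationConfig,
        }
        kwargs: dict = {}
        for key, sub_cls in sections.items():
            if key in data:
                sub = data.pop(key) or {}
                if key == "simulate":
                    for tup_key in ("snps_per_gene", "maf_range"):
                        if tup_key in sub:
                            sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = _build(sub_cls, sub, key)
        return _build(cls, {**data, **kwargs}, "top level")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        if cfg.seed != cfg.simulate.seed and "simulate" not in data:
            cfg.simulate.seed = cfg.seed
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["simulate"]["snps_per_gene"] = list(self.simulate.snps_per_gene)
        data["simulate"]["maf_range"] = list(self.simulate.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def for_fixture(cls, fixture_dir: str | Path, out_dir: str | Path, seed: int = 13) -> "PipelineConfig":
        """Config wired to the file layout of a synthetic fixture bundle."""
        d = Path(fixture_dir)
        cfg = cls(seed=seed, out_dir=str(out_dir))
        cfg.simulate.seed = seed
        cfg.inputs = InputPaths(
            platform1_pre=str(d / "platform1_pre.tsv"),
            platform1_post=str(d / "platform1_post.tsv"),
            platform2_pre=str(d / "platform2_pre.tsv"),
            platform2_post=str(d / "platform2_post.tsv"),
            gene_locations=str(d / "gene_locations.tsv"),
            gene_sets=str(d / "gene_sets.gmt"),
            reference_panel=str(d / "reference_panel.tsv"),
        )
        return cfg
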