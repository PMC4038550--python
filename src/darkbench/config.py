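"""Run configuration: one YAML document drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields as dc_fields

import yaml

from .imaging import CameraModel, FieldSpec
from .segmentation import SegmentationParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to rerun an experiment deterministically.

    ``scenarios`` lists the conditions to simulate/benchmark (names from the
    built-in catalogue or a user catalogue YAML); ``af_condition`` names the
    autofluorescence reference.  ``bypass_tolerance`` is the declared relative
    D/S tolerance between the imaging route and the population-level shortcut
    (imaging adds camera/segmentation noise on top of sampling noise).
    """

    master_seed: int = 0
    scenarios: list[str] = field(
        default_factory=lambda: ["pGFPamy@OD5", "pGFP_Star@OD5"])
    af_condition: str = "AF_GFP"
    scenario_file: str | None = None     # optional user catalogue (YAML)
    n_cells: int = 1000
    k_replicates: int = 1
    out_dir: str = "darkbench_out"
    use_imaging: bool = True
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    camera: CameraModel = field(default_factory=CameraModel)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    bg_dilation_px: int = 5
    min_cells: int = 500
    n_boot: int = 2000
    bypass_tolerance: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("field_spec", FieldSpec), ("camera", CameraModel),
                         ("seg_params", SegmentationParams)):
            if key in doc and isinstance(doc[key], dict):
                params = dict(doc[key])
                # YAML has no tuples; restore the size-range pairs
                for tup_key in ("cell_length_um", "cell_width_um"):
                    if tup_key in params and isinstance(params[tup_key], list):
                        params[tup_key] = tuple(params[tup_key])
                doc[key] = sub(**params)
        return cls(**doc)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(doc)
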