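"""Run configuration: thresholds, point tables and correction factors.

Every tunable number in the pipeline lives in one YAML document
(``fhdx/data/default_config.yaml``); :func:`load_config` parses it into
typed pydantic models and lets a user file override any subset of keys.
"""

from __future__ import annotations

import functools
import importlib.resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, Field


class DlcncConfig(BaseModel):
    ldl_bands: List[Tuple[float, int]]
    family_pcvd_or_hyperlipidemia_points: int = 1
    family_xanthoma_or_child_high_ldl_points: int = 2
    personal_premature_cad_points: int = 2
    personal_cerebral_or_peripheral_points: int = 1
    tendon_xanthoma_points: int = 6
    arcus_under_45_points: int = 4
    dna_variant_points: int = 8
    definite_above: int = 8
    probable_min: int = 6
    possible_min: int = 3
    binary_cutoff: int = 3
    score_family_pcvd_separately: bool = False
    include_genetic: bool = True
    pediatric_policy: Literal["flag", "suppress"] = "flag"


class ModifiedDlcncConfig(BaseModel):
    ldl_bands: List[Tuple[float, int]]


class SimonBroomeConfig(BaseModel):
    adult_ldl_cutoff: float = 4.9
    child_ldl_cutoff: float = 4.0
    include_relative_tendon_xanthoma: bool = True
    include_genetic: bool = True


class MedpedConfig(BaseModel):
    thresholds: Dict[str, Dict[str, float]]


class JfhmcConfig(BaseModel):
    adult_ldl_cutoff: float = 4.7
    child_ldl_cutoff: float = 3.6
    hofh_tc_cutoff: float = 15.5


class HkPanelConfig(BaseModel):
    adult_ldl_cutoff: float = 5.0
    adult_ldl_cutoff_with_history: float = 4.5
    child_ldl_cutoff: float = 4.9
    child_ldl_cutoff_with_history: float = 3.6


class CriteriaConfig(BaseModel):
    dlcnc: DlcncConfig
    modified_dlcnc: ModifiedDlcncConfig
    simon_broome: SimonBroomeConfig = Field(default_factory=SimonBroomeConfig)
    medped: MedpedConfig
    jfhmc: JfhmcConfig = Field(default_factory=JfhmcConfig)
    hk_panel: HkPanelConfig = Field(default_factory=HkPanelConfig)


class LdlPolicyConfig(BaseModel):
    source: Literal["pretreatment_first", "peak_first"] = "pretreatment_first"


class IntensityConfig(BaseModel):
    factors: Dict[str, Dict[Union[int, float], float]]
    combination: Literal["multiplicative", "additive_reduction"] = "multiplicative"
    untreated_intensity: float = 1.0
    threshold: float = 1.8
    reduction_band: Tuple[float, float] = (0.40, 0.70)
    combined_ldl_cutoff: float = 5.5


class VariantsConfig(BaseModel):
    splice_offset_window: int = 5
    receptor_class_map: Dict[str, str]


class IoConfig(BaseModel):
    mgdl_input: bool = False
    ldl_plausible_max: float = 30.0


class RunConfig(BaseModel):
    criteria: CriteriaConfig
    ldl_policy: LdlPolicyConfig = Field(default_factory=LdlPolicyConfig)
    intensity: IntensityConfig
    variants: VariantsConfig
    io: IoConfig = Field(default_factory=IoConfig)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@functools.lru_cache(maxsize=1)
def _default_text() -> str:
    return (
        importlib.resources.files("fhdx.data")
        .joinpath("default_config.yaml")
        .read_text()
    )


@functools.lru_cache(maxsize=1)
def _default_model() -> RunConfig:
    return RunConfig.model_validate(yaml.safe_load(_default_text()))


def _default_dict() -> dict:
    return yaml.safe_load(_default_text())


def default_config() -> RunConfig:
    """The shipped default configuration (a fresh, mutable copy)."""
    return _default_model().model_copy(deep=True)


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load configuration, overlaying a user YAML file on the defaults."""
    data = _default_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        data = _deep_merge(data, user)
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Echo a run's full configuration to a YAML file (reproducibility)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
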