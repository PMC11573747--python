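"""Structured run configuration (YAML) with strict schema validation.

Unknown keys are rejected before any computation starts, so a typo in a
config file fails fast instead of silently running with a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import pydantic
import yaml

from .conditions import Condition
from .demux import BarcodePlan
from .errors import ConfigError
from .events import ChannelMap
from .gating import GatePredicate, PopulationGate
from .metrics import POLICY_MEAN_FIRST


class _Strict(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class ChannelsConfig(_Strict):
    ncaa_signal: str
    barcode_a: Optional[str] = None
    barcode_b: Optional[str] = None
    markers: dict[str, str] = {}
    viability: Optional[str] = None

    def to_channel_map(self) -> ChannelMap:
        return ChannelMap(
            ncaa_signal=self.ncaa_signal,
            barcode_a=self.barcode_a,
            barcode_b=self.barcode_b,
            markers=dict(self.markers),
            viability=self.viability,
        )


class InputFileConfig(_Strict):
    path: str
    format: Optional[Literal["csv", "fcs"]] = None
    condition: Optional[str] = None  # unpooled runs: label of this file
    sample_id: Optional[str] = None
    donor_id: Optional[str] = None
    tissue: Optional[str] = None
    stimulation: Optional[str] = None
    replicate_id: Optional[str] = None


class InputsConfig(_Strict):
    pooled: bool = True
    files: list[InputFileConfig] = []


class BarcodeConfig(_Strict):
    # keys "hi/hi", "hi/lo", "lo/hi", "lo/lo" -> condition labels
    plan: dict[str, str] = {
        "hi/hi": "DMSO",
        "hi/lo": "2DG",
        "lo/hi": "Oligo",
        "lo/lo": "2DG+Oligo",
    }
    expected_ratio: float = 100.0
    guard: float = 0.1
    min_events: int = 50
    min_events_condition: int = 100
    hard_floor: int = 25

    def to_plan(self) -> BarcodePlan:
        mapping = {}
        for key, label in self.plan.items():
            parts = key.split("/")
            if len(parts) != 2 or not all(p in ("hi", "lo") for p in parts):
                raise ConfigError(f"bad barcode plan key {key!r}; use e.g. 'hi/lo'")
            try:
                mapping[(parts[0], parts[1])] = Condition.from_label(label)
            except ValueError as err:
                raise ConfigError(str(err)) from None
        return BarcodePlan(mapping=mapping, expected_ratio=self.expected_ratio)


class GatePredicateConfig(_Strict):
    marker: str
    op: Literal[">", "<", ">=", "<="]
    cutoff: float


class GateConfig(_Strict):
    name: str
    predicates: list[GatePredicateConfig]
    parent: Optional[str] = None

    def to_gate(self) -> PopulationGate:
        return PopulationGate(
            name=self.name,
            predicates=tuple(
                GatePredicate(marker=p.marker, op=p.op, cutoff=p.cutoff)
                for p in self.predicates
            ),
            parent=self.parent,
        )


class MetricsConfig(_Strict):
    statistic: Literal["geometric", "arithmetic"] = "geometric"
    aggregation: Literal[
        "mean_of_gmfi_before_formula", "profile_per_replicate_then_mean"
    ] = POLICY_MEAN_FIRST
    clamp: bool = False  # reporting-layer clamp to [0, 100]
    min_events: int = 100
    min_events_error: int = 25
    resolution_floor: Optional[float] = None  # None -> auto (3x pooled gMFI SE)
    auto_floor_factor: float = 3.0


class StatsConfig(_Strict):
    pca: bool = True
    scale: bool = True  # unit-variance feature scaling before PCA
    n_components: Optional[int] = None
    compare_stimulations: bool = True  # vs-control tests when design allows
    control: str = "Medium"
    n_mc: int = 20000


class RunConfig(_Strict):
    channels: ChannelsConfig
    inputs: InputsConfig = InputsConfig()
    barcode: BarcodeConfig = BarcodeConfig()
    gates: list[GateConfig] = []
    metrics: MetricsConfig = MetricsConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0

    def gate_list(self) -> list[PopulationGate]:
        return [g.to_gate() for g in self.gates]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: no such config file")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: invalid YAML: {err}") from None
    return parse_config(raw if raw is not None else {})


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as err:
        raise ConfigError(f"invalid configuration: {err}") from None
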