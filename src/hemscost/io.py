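"""Run configuration, currency normalization and CSV serialization."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .cost_model import FIXED_DENOMINATOR_MODES, SECONDARY_MATERIAL_MODES
from .scenario_engine import SCENARIO_IDS, ScenarioResultRow, table_frame

__all__ = [
    "RunConfig",
    "load_config",
    "parse_currency",
    "format_currency",
    "write_table_csv",
    "read_table_csv",
]

_GERMAN_CURRENCY = re.compile(r"^-?\d{1,3}(\.\d{3})*(,\d+)?$")

DEFAULT_X_VALUES = (900, 1200, 1500)


def parse_currency(value: Union[str, int, float]) -> float:
    """Normalize a euro amount; German formatting is accepted on input.

    ``"1.697.546,20"``, ``"43,94"`` and ``"1697546.20"`` all parse; output is
    always a plain float with "." decimal separator semantics.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip().replace("€", "").replace(" ", "")
    if not text:
        raise ValueError("empty currency value")
    if _GERMAN_CURRENCY.match(text) and ("," in text or text.count(".") > 0):
        text = text.replace(".", "").replace(",", ".")
    elif "," in text and "." not in text:
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"cannot parse currency value {value!r}") from exc


def format_currency(value: float) -> str:
    """Two decimals, '.' separator, no thousands grouping."""
    return f"{value:.2f}"


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings for the command-line interface."""

    scenario_ids: tuple[str, ...] = tuple(SCENARIO_IDS)
    x_values: tuple[int, ...] = DEFAULT_X_VALUES
    price_per_minute: float = 70.0
    secondary_material_mode: str = "formula"
    fixed_denominator: str = "primary_minutes"
    daytime_personnel_cost: Optional[float] = None
    output_dir: Path = Path("results")
    verbosity: int = 0

    def __post_init__(self) -> None:
        unknown = [sid for sid in self.scenario_ids if sid not in SCENARIO_IDS]
        if unknown:
            raise ValueError(f"unknown scenario id(s): {', '.join(unknown)}")
        if not self.scenario_ids:
            raise ValueError("at least one scenario id is required")
        if not self.x_values or any(x < 1 for x in self.x_values):
            raise ValueError("x values must be a nonempty list of integers >= 1")
        if self.secondary_material_mode not in SECONDARY_MATERIAL_MODES:
            raise ValueError(
                f"secondary_material_mode must be one of {SECONDARY_MATERIAL_MODES}"
            )
        if self.fixed_denominator not in FIXED_DENOMINATOR_MODES:
            raise ValueError(f"fixed_denominator must be one of {FIXED_DENOMINATOR_MODES}")
        if self.price_per_minute < 0:
            raise ValueError("price_per_minute must be >= 0")


def _parse_x(value, *, where: str) -> tuple[int, ...]:
    if value is None:
        return DEFAULT_X_VALUES
    if isinstance(value, str):
        try:
            return tuple(int(part) for part in value.replace(" ", "").split(",") if part)
        except ValueError as exc:
            raise ValueError(f"{where}: cannot parse x list {value!r}") from exc
    if isinstance(value, Mapping):
        try:
            lo, hi = int(value["min"]), int(value["max"])
        except KeyError as exc:
            raise ValueError(f"{where}: x range needs 'min' and 'max'") from exc
        step = int(value.get("step", 1))
        if not (1 <= lo <= hi and step >= 1):
            raise ValueError(f"{where}: invalid x range {value!r}")
        return tuple(range(lo, hi + 1, step))
    if isinstance(value, Sequence):
        return tuple(int(v) for v in value)
    if isinstance(value, int):
        return (value,)
    raise ValueError(f"{where}: unsupported x specification {value!r}")


def _parse_scenarios(value, *, where: str) -> tuple[str, ...]:
    if value is None or value == "all":
        return tuple(SCENARIO_IDS)
    if isinstance(value, str):
        ids = tuple(part for part in value.replace(" ", "").split(",") if part)
    elif isinstance(value, Sequence):
        ids = tuple(str(v) for v in value)
    else:
        raise ValueError(f"{where}: unsupported scenario selection {value!r}")
    unknown = [sid for sid in ids if sid not in SCENARIO_IDS]
    if unknown:
        raise ValueError(f"{where}: unknown scenario id(s): {', '.join(unknown)}")
    return ids


_CONFIG_KEYS = {
    "scenarios",
    "x",
    "price_per_minute",
    "secondary_material_mode",
    "fixed_denominator",
    "daytime_personnel_cost",
    "output_dir",
    "verbosity",
}


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Defaults are applied for every missing key (tariff 70 €/min,
    formula-faithful modes, x sweep 900/1200/1500, all scenarios).  Errors
    name the offending key.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text("utf-8"))
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: cannot parse configuration: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = sorted(set(doc) - _CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {', '.join(unknown)}")
    override = doc.get("daytime_personnel_cost")
    return RunConfig(
        scenario_ids=_parse_scenarios(doc.get("scenarios"), where=f"{path}:scenarios"),
        x_values=_parse_x(doc.get("x"), where=f"{path}:x"),
        price_per_minute=parse_currency(doc.get("price_per_minute", 70.0)),
        secondary_material_mode=str(doc.get("secondary_material_mode", "formula")),
        fixed_denominator=str(doc.get("fixed_denominator", "primary_minutes")),
        daytime_personnel_cost=None if override is None else parse_currency(override),
        output_dir=Path(doc.get("output_dir", "results")),
        verbosity=int(doc.get("verbosity", 0)),
    )


def write_table_csv(rows: Sequence[ScenarioResultRow], destination) -> None:
    """Write a cost-overview table as CSV (2-decimal currency, '.' decimals)."""
    frame = table_frame(rows)
    frame.to_csv(destination, index=False, float_format="%.2f", lineterminator="\n")


def read_table_csv(source) -> pd.DataFrame:
    """Reload a cost-overview CSV produced by :func:`write_table_csv`."""
    return pd.read_csv(source)
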