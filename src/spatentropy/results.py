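"""Common result container for all entropy measures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

__all__ = ["EntropyResult", "validate_result_dict"]


@dataclass
class EntropyResult:
    """An entropy value in nats together with its range and relative form.

    ``relative`` is the measure's documented normalisation (for most
    measures value / range_max); ``table`` is the frequency table the value
    was computed from and supports ``to_records()``.
    """

    measure: str
    value: float
    range_min: float
    range_max: float
    relative: float
    table: Any = None
    meta: dict = field(default_factory=dict)
    units: str = "nats"

    def to_dict(self) -> dict:
        out = {
            "measure": self.measure,
            "value": float(self.value),
            "units": self.units,
            "range": [float(self.range_min), float(self.range_max)],
            "relative": float(self.relative),
            "meta": dict(self.meta),
        }
        if self.table is not None and hasattr(self.table, "to_records"):
            out["table"] = self.table.to_records()
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def table_to_csv(self, path) -> None:
        import csv as _csv

        records = self.table.to_records() if self.table is not None else []
        with open(path, "w", newline="") as fh:
            if not records:
                fh.write("")
                return
            writer = _csv.DictWriter(fh, fieldnames=list(records[0]))
            writer.writeheader()
            writer.writerows(records)

    def __str__(self) -> str:  # human summary, 2 decimals like printed tables
        return (f"{self.measure}: {self.value:.2f} {self.units} "
                f"(range [{self.range_min:.2f}, {self.range_max:.2f}], "
                f"relative {self.relative:.2f})")


_REQUIRED = {"measure": str, "value": (int, float), "units": str,
             "range": list, "relative": (int, float), "meta": dict}


def validate_result_dict(obj: dict) -> None:
    """Check a serialised result against the published shape; raises ValueError."""
    for key, typ in _REQUIRED.items():
        if key not in obj:
            raise ValueError(f"result JSON missing key {key!r}")
        if not isinstance(obj[key], typ):
            raise ValueError(f"result JSON key {key!r} has wrong type")
    if len(obj["range"]) != 2:
        raise ValueError("result JSON 'range' must have two elements")
    if "table" in obj:
        if not isinstance(obj["table"], list):
            raise ValueError("result JSON 'table' must be a list of records")
        for rec in obj["table"]:
            if not isinstance(rec, dict):
                raise ValueError("result JSON table records must be objects")
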