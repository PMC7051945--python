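"""Model parameter bookkeeping.

Every symbol used by a rate expression lives in a :class:`ParameterSet`:
a named table of values with unit strings, an optional sampling
distribution (for virtual-patient generation) and a provenance tag
distinguishing literature-derived values from documented assumptions.

The model's internal time unit is the day.  Parameter tables may carry
pharmacokinetic constants in per-hour or per-second units as published;
:meth:`ParameterSet.in_model_units` converts them on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

PROVENANCES = ("supplementary-table", "assumed", "fitted")
DIST_KINDS = ("uniform", "loguniform", "normal")

# unit-string rewrites applied by in_model_units(); factor multiplies the value
_UNIT_TO_DAY = {
    "1/h": ("1/d", 24.0),
    "L/h": ("L/d", 24.0),
    "mL/h": ("mL/d", 24.0),
    "ng/h": ("ng/d", 24.0),
    "1/s": ("1/d", 86400.0),
    "1/nM/s": ("1/nM/d", 86400.0),
    "um^2/molec/s": ("um^2/molec/d", 86400.0),
    "h": ("d", 1.0 / 24.0),
}


@dataclass(frozen=True)
class ParameterEntry:
    """One named constant with unit, provenance, and optional distribution."""

    name: str
    value: float
    unit: str = "dimensionless"
    dist_kind: str | None = None
    dist_low: float | None = None  # mean when dist_kind == "normal"
    dist_high: float | None = None  # sd when dist_kind == "normal"
    provenance: str = "assumed"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r} for {self.name}")
        if self.dist_kind is not None:
            if self.dist_kind not in DIST_KINDS:
                raise ValueError(f"unknown distribution {self.dist_kind!r} for {self.name}")
            if self.dist_low is None or self.dist_high is None:
                raise ValueError(f"distribution bounds missing for {self.name}")
            if not (math.isfinite(self.dist_low) and math.isfinite(self.dist_high)):
                raise ValueError(f"distribution bounds not finite for {self.name}")
            if self.dist_kind in ("uniform", "loguniform") and not self.dist_low < self.dist_high:
                raise ValueError(f"require low < high for {self.name}")

    @property
    def sampled(self) -> bool:
        return self.dist_kind is not None


class ParameterSet:
    """Ordered mapping of :class:`ParameterEntry` keyed by symbol name."""

    def __init__(self, entries: Iterable[ParameterEntry] = ()):
        self._entries: dict[str, ParameterEntry] = {}
        for e in entries:
            self.add(e)

    # -- mapping surface -------------------------------------------------
    def add(self, entry: ParameterEntry) -> None:
        if entry.name in self._entries:
            raise ValueError(f"duplicate parameter {entry.name!r}")
        self._entries[entry.name] = entry

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[ParameterEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, name: str) -> ParameterEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"unknown parameter symbol {name!r}") from None

    def __getitem__(self, name: str) -> float:
        return self.entry(name).value

    def names(self) -> list[str]:
        return list(self._entries)

    # -- transforms ------------------------------------------------------
    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New set with values replaced; unknown names are an error."""
        out = ParameterSet()
        for e in self:
            out.add(replace(e, value=float(overrides[e.name])) if e.name in overrides else e)
        unknown = set(overrides) - set(self._entries)
        if unknown:
            raise KeyError(f"unknown parameter symbol(s) {sorted(unknown)!r}")
        return out

    def in_model_units(self) -> "ParameterSet":
        """Convert per-hour / per-second constants to per-day at load time."""
        out = ParameterSet()
        for e in self:
            if e.unit in _UNIT_TO_DAY:
                unit, factor = _UNIT_TO_DAY[e.unit]
                lo = e.dist_low * factor if e.dist_low is not None else None
                hi = e.dist_high * factor if e.dist_high is not None else None
                out.add(replace(e, value=e.value * factor, unit=unit, dist_low=lo, dist_high=hi))
            else:
                out.add(e)
        return out

    def filter_provenance(self, provenance: str) -> list[ParameterEntry]:
        return [e for e in self if e.provenance == provenance]

    def sampled_entries(self) -> list[ParameterEntry]:
        return [e for e in self if e.sampled]

    # -- I/O -------------------------------------------------------------
    _COLUMNS = ["name", "value", "unit", "dist_kind", "dist_low", "dist_high", "provenance"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "value": e.value,
                    "unit": e.unit,
                    "dist_kind": e.dist_kind,
                    "dist_low": e.dist_low,
                    "dist_high": e.dist_high,
                    "provenance": e.provenance,
                }
                for e in self
            ],
            columns=self._COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        records = self.to_frame().to_dict(orient="records")
        for r in records:
            for k, v in list(r.items()):
                if isinstance(v, float) and math.isnan(v):
                    r[k] = None
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "ParameterSet":
        out = cls()
        for r in records:
            kind = r.get("dist_kind")
            if isinstance(kind, float) and math.isnan(kind):
                kind = None
            kind = kind or None

            def _f(key):
                v = r.get(key)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    return None
                return float(v)

            out.add(
                ParameterEntry(
                    name=str(r["name"]),
                    value=float(r["value"]),
                    unit=str(r.get("unit", "dimensionless")),
                    dist_kind=kind,
                    dist_low=_f("dist_low"),
                    dist_high=_f("dist_high"),
                    provenance=str(r.get("provenance", "assumed")),
                )
            )
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterSet":
        import pandas as pd

        return cls.from_records(pd.read_csv(path).to_dict(orient="records"))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_records(json.loads(Path(path).read_text()))
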