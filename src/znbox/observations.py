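"""Observation tables: per-compartment delta66Zn with confidence half-widths.

The half-width (``ci_halfwidth``, per mil) plays the role of an acceptance
band in the sweep fit: a parameter set is kept only if its predicted steady
state falls within every constrained compartment's band.  Rows can be
flagged ``excluded`` (e.g. kidney, used as an interface rather than fitted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import BoxModel

__all__ = ["Observation", "ObservationTable", "load_observations", "save_observations"]


@dataclass(frozen=True)
class Observation:
    compartment: str
    delta: float          # observed delta66Zn, per mil vs JMC-Lyon
    ci_halfwidth: float   # 2SE confidence half-width, per mil
    n: int = 1            # replicate count behind the mean
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.ci_halfwidth <= 0:
            raise ValueError(
                f"observation for {self.compartment!r} needs ci_halfwidth > 0"
            )
        if self.n < 1:
            raise ValueError(f"observation for {self.compartment!r} needs n >= 1")


class ObservationTable:
    """Ordered collection of observations with name-based lookup."""

    def __init__(self, rows: Iterable[Observation]) -> None:
        self.rows = list(rows)
        self._by_name = {r.compartment: r for r in self.rows}
        if len(self._by_name) != len(self.rows):
            raise ValueError("duplicate compartment in observation table")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def lookup(self, name: str) -> Observation:
        return self._by_name[name]

    @property
    def constrained(self) -> list[Observation]:
        """Rows that act as fit constraints (not excluded)."""
        return [r for r in self.rows if not r.excluded]

    def unmatched(self, model: BoxModel) -> list[str]:
        """Observation names that do not resolve to a model compartment."""
        names = {c.name for c in model.compartments}
        return [r.compartment for r in self.rows if r.compartment not in names]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": [r.compartment for r in self.rows],
                "delta66Zn": [r.delta for r in self.rows],
                "ci_halfwidth": [r.ci_halfwidth for r in self.rows],
                "n": [r.n for r in self.rows],
                "excluded": [int(r.excluded) for r in self.rows],
            }
        )


def load_observations(path: str | Path) -> ObservationTable:
    """Read a CSV with header ``compartment,delta66Zn,ci_halfwidth,n[,excluded]``."""
    df = pd.read_csv(path)
    required = {"compartment", "delta66Zn", "ci_halfwidth", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV {path} missing columns {sorted(missing)}")
    rows = [
        Observation(
            compartment=str(r.compartment),
            delta=float(r.delta66Zn),
            ci_halfwidth=float(r.ci_halfwidth),
            n=int(r.n),
            excluded=bool(int(getattr(r, "excluded", 0))),
        )
        for r in df.itertuples(index=False)
    ]
    return ObservationTable(rows)


def save_observations(table: ObservationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)
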