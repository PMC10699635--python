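"""Per-sample, per-marker SNP state table ({ancestral, derived, missing})."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

ANCESTRAL = "A"
DERIVED = "D"
MISSING = "."
VALID_STATES = frozenset({ANCESTRAL, DERIVED, MISSING})


@dataclass
class SNPGenotypeTable:
    """Wide table of SNP states: rows = samples, columns = markers.

    `states` holds one of "A" (ancestral), "D" (derived) or "." (missing)
    per cell. Optional per-sample population/group labels ride along for
    structure analyses and grouped frequency tables.
    """

    states: pd.DataFrame
    populations: pd.Series | None = None
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - VALID_STATES
        if bad:
            raise ValueError(f"invalid SNP states {sorted(bad)!r}; allowed: A, D, .")
        if self.states.index.has_duplicates:
            raise ValueError("duplicate sample ids in genotype table")
        for name in ("populations", "groups"):
            series = getattr(self, name)
            if series is not None:
                setattr(self, name, series.reindex(self.states.index))

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def markers(self) -> list[str]:
        return list(self.states.columns)

    def state(self, sample: str, marker: str) -> str:
        return self.states.at[sample, marker]

    def carriers(self, marker: str) -> list[str]:
        """Samples derived at `marker`."""
        col = self.states[marker]
        return list(col.index[col == DERIVED])

    def n_genotyped(self, marker: str) -> int:
        return int((self.states[marker] != MISSING).sum())

    def label(self, grouping: str) -> pd.Series:
        if grouping == "population":
            series = self.populations
        elif grouping == "group":
            series = self.groups
        else:
            raise KeyError(f"unknown grouping label {grouping!r}")
        if series is None:
            raise KeyError(f"grouping {grouping!r} not attached to this table")
        return series

    def restrict_markers(self, markers) -> "SNPGenotypeTable":
        known = [m for m in markers if m in self.states.columns]
        unknown = sorted(set(markers) - set(known))
        if unknown:
            warnings.warn(f"ignoring unknown markers: {unknown}", stacklevel=2)
        return SNPGenotypeTable(self.states[known], self.populations, self.groups)
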