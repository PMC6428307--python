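"""Variable metadata and the mixed-type dataset container.

A dataset is a plain :class:`pandas.DataFrame` bound to one
:class:`VariableSpec` per column.  The spec — not the data — is the source
of truth for a variable's type and its ordered level set; degrees of
freedom used in parameter counting are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

VTYPES = ("continuous", "nominal", "ordinal")


class MixedDataError(ValueError):
    """Raised when data and variable specs disagree."""


@dataclass(frozen=True)
class VariableSpec:
    """Name, type and (for categoricals) ordered level set of one variable.

    ``levels`` must be empty for continuous variables and hold at least two
    distinct labels otherwise; for ordinal variables the declared order of
    ``levels`` carries the total order of the categories.
    """

    name: str
    vtype: str
    levels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise MixedDataError(
                f"unknown variable type {self.vtype!r} for {self.name!r}; "
                f"expected one of {VTYPES}"
            )
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if self.vtype == "continuous":
            if levels:
                raise MixedDataError(
                    f"continuous variable {self.name!r} must not declare levels"
                )
        else:
            if len(levels) < 2:
                raise MixedDataError(
                    f"{self.vtype} variable {self.name!r} needs >= 2 levels, "
                    f"got {levels!r}"
                )
            if len(set(levels)) != len(levels):
                raise MixedDataError(
                    f"duplicate levels in {self.name!r}: {levels!r}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.vtype != "continuous"

    @property
    def n_levels(self) -> int:
        """d_X: number of distinct values (0 for continuous)."""
        return len(self.levels)

    @property
    def dof(self) -> int:
        """Degrees of freedom: 1 if continuous, d_X - 1 if categorical."""
        return 1 if self.vtype == "continuous" else len(self.levels) - 1


def dof(specs: Iterable[VariableSpec]) -> int:
    """Total degrees of freedom of a set of variables (empty set -> 0)."""
    return sum(s.dof for s in specs)


class MixedDataset:
    """An n-by-p sample table bound to one :class:`VariableSpec` per column.

    Validation at construction rejects missing values, columns without a
    spec, and categorical cells outside their declared level set, so that
    downstream regression code never has to re-check.
    """

    def __init__(self, samples: pd.DataFrame, specs: Sequence[VariableSpec]):
        specs = tuple(specs)
        by_name = {s.name: s for s in specs}
        if len(by_name) != len(specs):
            raise MixedDataError("duplicate variable names in specs")
        missing = [c for c in samples.columns if c not in by_name]
        if missing:
            raise MixedDataError(f"columns without a spec: {missing}")
        absent = [s.name for s in specs if s.name not in samples.columns]
        if absent:
            raise MixedDataError(f"specs without a data column: {absent}")
        if len(samples) < 1:
            raise MixedDataError("dataset must contain at least one row")
        # column order follows the spec order
        samples = samples.loc[:, [s.name for s in specs]]
        for s in specs:
            col = samples[s.name]
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise MixedDataError(
                    f"missing value in column {s.name!r} (first at row {row})"
                )
            if s.is_categorical:
                bad = set(col.unique()) - set(s.levels)
                if bad:
                    raise MixedDataError(
                        f"column {s.name!r} contains values outside its "
                        f"declared levels: {sorted(map(str, bad))}"
                    )
            else:
                if not pd.api.types.is_numeric_dtype(col):
                    raise MixedDataError(
                        f"continuous column {s.name!r} is not numeric"
                    )
        self.samples = samples.reset_index(drop=True)
        self.specs = specs
        self._by_name = by_name

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def p(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise MixedDataError(f"no variable named {name!r}") from None

    def column(self, name: str) -> pd.Series:
        self.spec(name)
        return self.samples[name]

    def __repr__(self) -> str:
        kinds = ", ".join(f"{s.name}:{s.vtype[0]}" for s in self.specs)
        return f"MixedDataset(n={self.n}, p={self.p}, [{kinds}])"
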