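"""File formats: CSV data + JSON type sidecar, edge-list graphs, configs.

The type sidecar is mandatory — nominal and ordinal columns are
indistinguishable in a CSV, yet they select different regression
families, so guessing types from the data is refused by design.
Dialect is fixed (comma separator, ``.`` decimal point, UTF-8) so that a
write/read round trip reproduces a dataset exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .graphs import GraphError, Pdag
from .variables import MixedDataError, MixedDataset, VariableSpec


def write_dataset(ds: MixedDataset, data_path, types_path) -> None:
    # shortest round-trippable float representation: read(write(ds)) == ds
    ds.samples.to_csv(data_path, index=False,
                      float_format=lambda v: repr(float(v)))
    types = {
        s.name: {"vtype": s.vtype, "levels": list(s.levels)}
        for s in ds.specs
    }
    Path(types_path).write_text(json.dumps(types, indent=1) + "\n")


def read_dataset(data_path, types_path) -> MixedDataset:
    """Load a CSV table with its JSON type sidecar into a validated dataset.

    Categorical columns are read as strings and checked against the
    declared levels; the level order is the declared one, not the order
    of appearance in the file.
    """
    types = json.loads(Path(types_path).read_text())
    dtypes = {name: (float if meta["vtype"] == "continuous" else str)
              for name, meta in types.items()}
    table = pd.read_csv(data_path, dtype=dtypes, float_precision="round_trip")
    missing = [c for c in table.columns if c not in types]
    if missing:
        raise MixedDataError(
            f"columns present in {data_path} but absent from the types "
            f"file: {missing}"
        )
    specs = [
        VariableSpec(name, meta["vtype"], tuple(meta.get("levels", ())))
        for name, meta in types.items()
    ]
    return MixedDataset(table, specs)


def write_graph(pdag: Pdag, path) -> None:
    """Edge-list text format: ``A -> B`` directed, ``A -- B`` undirected."""
    lines = [f"# nodes: {','.join(pdag.nodes)}"]
    for a, b in sorted(pdag.directed):
        lines.append(f"{a} -> {b}")
    for e in sorted(pdag.undirected, key=sorted):
        a, b = sorted(e)
        lines.append(f"{a} -- {b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path) -> Pdag:
    nodes = None
    directed, undirected = [], []
    seen = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("nodes:"):
                names = body[len("nodes:"):].strip()
                nodes = [v for v in names.split(",") if v]
            continue
        for sep, bucket in ((" -> ", directed), (" -- ", undirected)):
            if sep in line:
                a, _, b = line.partition(sep)
                a, b = a.strip(), b.strip()
                pair = frozenset((a, b))
                if pair in seen:
                    raise GraphError(
                        f"{path}:{lineno}: duplicate edge {a!r}-{b!r}")
                seen.add(pair)
                bucket.append((a, b))
                break
        else:
            raise GraphError(f"{path}:{lineno}: malformed edge line {raw!r}")
    if nodes is None:
        raise GraphError(f"{path}: missing '# nodes:' header")
    return Pdag(nodes, directed=directed, undirected=undirected)


@dataclasses.dataclass
class RunConfig:
    """Echoed next to every artifact so a run can be reproduced exactly."""

    command: str
    seed: Optional[int] = None
    alpha: float = 0.01
    method: str = "mm"
    max_k: Optional[int] = None
    params: dict = dataclasses.field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
            + "\n"
        )

    @classmethod
    def read(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
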