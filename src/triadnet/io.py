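"""Network readers/writers and the seeded fixture generator.

Pajek ``.net`` is the primary interchange format (blockmodeling tooling
traditionally consumes it); a two-column arc-list CSV and a dense 0/1
adjacency CSV are kept for spreadsheet inspection.  Units are 0-based in
memory and 1-based in Pajek files.  Writers emit arcs in lexicographic
order so outputs are byte-stable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .blockmodels import BLOCKMODEL_TYPES, build_ideal, default_spec, perturb
from .netcore import MAN_LABELS, Network, triad_census

__all__ = ["read_network", "write_network", "make_fixtures", "FORMATS"]

FORMATS = ("pajek", "edgelist_csv", "adjacency_csv")

_SUFFIX_FORMAT = {".net": "pajek", ".paj": "pajek", ".csv": "edgelist_csv"}


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in FORMATS:
            raise ValueError(f"unknown format {format!r}; use one of {FORMATS}")
        return format
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer format from suffix {path.suffix!r}; pass format=")


def _read_pajek(path: Path) -> Network:
    import networkx as nx

    with open(path, encoding="utf-8") as fh:
        g = nx.parse_pajek(fh.read())
    # parse_pajek returns a MultiGraph/MultiDiGraph keyed by vertex label;
    # recover the 1-based ids it stores in the "id" attribute.
    ids = nx.get_node_attributes(g, "id")
    if len(ids) != g.number_of_nodes():
        raise ValueError(f"{path}: malformed Pajek header (missing vertex ids)")
    n = g.number_of_nodes()
    order = {}
    for node, vid in ids.items():
        i = int(vid) - 1
        if not 0 <= i < n:
            raise ValueError(f"{path}: vertex id {vid} out of range 1..{n}")
        order[node] = i
    arcs = set()
    dupes = 0
    for u, v in g.edges():
        i, j = order[u], order[v]
        if i == j:
            raise ValueError(f"{path}: self-loop on vertex {i + 1}")
        if (i, j) in arcs:
            dupes += 1
        arcs.add((i, j))
    if dupes:
        warnings.warn(f"{path}: collapsed {dupes} duplicate arcs")
    return Network(n, arcs)


def read_network(path, format: str | None = None) -> Network:
    """Read a directed network from Pajek, arc-list CSV or adjacency CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pajek":
        return _read_pajek(path)
    if fmt == "edgelist_csv":
        n_header = None
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        if first.startswith("# vertices:"):
            n_header = int(first.split(":")[1])
        df = pd.read_csv(path, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need columns (from, to)")
        src = df.iloc[:, 0].to_numpy(dtype=int) - 1
        dst = df.iloc[:, 1].to_numpy(dtype=int) - 1
        n = int(max(src.max(initial=-1), dst.max(initial=-1)) + 1)
        if n_header is not None:
            if n_header < n:
                raise ValueError(f"{path}: arc ids exceed declared vertex count")
            n = n_header
        pairs = list(zip(src.tolist(), dst.tolist()))
        if len(set(pairs)) < len(pairs):
            warnings.warn(f"{path}: collapsed duplicate arcs")
        return Network(n, set(pairs))
    # adjacency_csv
    A = pd.read_csv(path, header=None).to_numpy()
    return Network.from_adjacency(A)


def write_network(net: Network, path, format: str | None = None) -> None:
    """Write a network with deterministic (lexicographic) arc ordering."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pajek":
        lines = [f"*Vertices {net.n}"]
        lines += [f'{i + 1} "v{i + 1}"' for i in range(net.n)]
        lines.append("*Arcs")
        lines += [f"{i + 1} {j + 1}" for i, j in net.arcs()]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "edgelist_csv":
        df = pd.DataFrame(net.arcs(), columns=["from", "to"]) + 1
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# vertices: {net.n}\n")
            df.to_csv(fh, index=False)
    else:
        pd.DataFrame(net.A).to_csv(path, index=False, header=False)


def make_fixtures(out_dir, seed=0) -> list[Path]:
    """Write the 7 default ideal networks, their LE in {0.25, 0.5, 1}
    perturbations, and censuses; returns the created paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    created = []
    for bm in BLOCKMODEL_TYPES:
        spec = default_spec(bm)
        ideal = build_ideal(spec)
        variants = {"LE0": ideal}
        for le in (0.25, 0.5, 1.0):
            variants[f"LE{le:g}".replace(".", "_")] = perturb(
                ideal, spec, le, rng.integers(2**31))
        for tag, net in variants.items():
            p = out_dir / f"{bm}_{tag}.net"
            write_network(net, p)
            created.append(p)
            c = out_dir / f"{bm}_{tag}_census.csv"
            c.write_text("label,count\n" + triad_census(net).to_table() + "\n",
                         encoding="utf-8")
            created.append(c)
    return created
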