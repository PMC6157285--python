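"""Text formats: constraints files, DAG edge lists, GraphViz DOT, scan tables.

All formats are line-oriented plain text. The constraints file uses the
directives ``whitelist FROM TO``, ``blacklist FROM TO`` and
``no-parents NODE`` with ``#`` comments. DAGs are stored as an edge-list
TSV preceded by a ``# node NAME KIND`` header block. DOT output follows
the figure convention of the analysis: discrete nodes as boxes,
continuous nodes as ellipses; averaged networks draw edge width
proportional to strength and label each arrow with its direction
probability.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .average import AverageNetwork
from .bn import ConstraintSet, Dag, Node
from .cohort import SchemaError

__all__ = [
    "read_constraints",
    "write_constraints",
    "read_dag",
    "write_dag",
    "dag_to_dot",
    "average_to_dot",
    "write_scan",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# constraints


def read_constraints(path: str | Path) -> ConstraintSet:
    whitelist, blacklist, no_parents = set(), set(), set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "whitelist" and len(parts) == 3:
            whitelist.add((parts[1], parts[2]))
        elif parts[0] == "blacklist" and len(parts) == 3:
            blacklist.add((parts[1], parts[2]))
        elif parts[0] == "no-parents" and len(parts) == 2:
            no_parents.add(parts[1])
        else:
            raise SchemaError(f"{path}:{lineno}: unrecognized directive {line!r}")
    return ConstraintSet(
        whitelist=frozenset(whitelist),
        blacklist=frozenset(blacklist),
        no_parent_nodes=frozenset(no_parents),
    )


def write_constraints(constraints: ConstraintSet, path: str | Path) -> None:
    lines = []
    for u, v in sorted(constraints.whitelist):
        lines.append(f"whitelist {u} {v}")
    for u, v in sorted(constraints.blacklist):
        lines.append(f"blacklist {u} {v}")
    for n in sorted(constraints.no_parent_nodes):
        lines.append(f"no-parents {n}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DAG edge lists


def write_dag(dag: Dag, path: str | Path) -> None:
    lines = [f"# node {n.name} {n.kind}" for n in dag.nodes]
    lines.append("parent\tchild")
    lines.extend(f"{u}\t{v}" for u, v in dag.edges())
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_dag(path: str | Path) -> Dag:
    nodes, edges = [], []
    saw_header = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# node "):
            parts = line.split()
            if len(parts) != 4:
                raise SchemaError(f"{path}:{lineno}: malformed node line {line!r}")
            nodes.append(Node(parts[2], parts[3]))
        elif line.startswith("#"):
            continue
        elif line == "parent\tchild":
            saw_header = True
        else:
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: malformed edge line {line!r}")
            edges.append((parts[0], parts[1]))
    if not saw_header:
        raise SchemaError(f"{path}: missing 'parent\\tchild' header")
    return Dag(nodes, edges)


# ---------------------------------------------------------------------------
# DOT


def _dot_node(n: Node) -> str:
    shape = "box" if n.kind == "discrete" else "ellipse"
    return f'  "{n.name}" [shape={shape}];'


def dag_to_dot(dag: Dag) -> str:
    lines = ["digraph network {"]
    lines += [_dot_node(n) for n in dag.nodes]
    lines += [f'  "{u}" -> "{v}";' for u, v in dag.edges()]
    lines.append("}")
    return "\n".join(lines) + "\n"


def average_to_dot(avg: AverageNetwork, cutoff: float | None = None) -> str:
    """DOT rendering of the (filtered) averaged network.

    Edge pen-width scales with strength; the label is the direction
    probability of the drawn orientation. Pairs below the cutoff (or the
    network's own threshold) are omitted.
    """
    cutoff = avg.threshold if cutoff is None else cutoff
    lines = ["digraph average_network {"]
    lines += [_dot_node(n) for n in avg.nodes]
    pairs = avg.retained(cutoff) if cutoff is not None else avg.pairs()
    for a, b in pairs:
        u, v = (a, b) if avg.direction.get((a, b), 0.0) >= 0.5 else (b, a)
        s = avg.strength[(a, b)]
        d = avg.direction[(u, v)]
        lines.append(
            f'  "{u}" -> "{v}" [penwidth={1 + 4 * s:.3f}, label="{d:.2f}", fontcolor=red];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scan results


def write_scan(result, path: str | Path) -> None:
    """Association scan as TSV with a '#'-prefixed summary block on top."""
    header = [
        f"# n_markers={result.m}",
        f"# lambda_gc={result.lambda_gc!r}",
        f"# bonferroni={result.bonferroni!r}",
        f"# alpha={result.alpha!r}",
        f"# skipped={','.join(result.skipped)}",
    ]
    body = result.table.to_csv(sep="\t", index=False)
    atomic_write_text(path, "\n".join(header) + "\n" + body)


def read_scan_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
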