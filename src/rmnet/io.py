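"""Readers and writers for the mothur and oligotyping tabular dialects.

mothur ``.relabund``/``.shared`` files are tab-delimited with the header
``label<TAB>Group<TAB>numOtus<TAB><taxon1>...`` and one row per sample; the
oligotyping ``matrix_percents.txt`` dialect has the header
``samples<TAB><oligo1>...`` with percentage cells.  All readers return the
package's canonical containers with abundances as fractions in [0, 1].

Files with several ``label`` blocks (multiple OTU definitions) are read from
the first block only, with a warning; OTU networks here use a single 97%
definition.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .matrix import AbundanceMatrix, CountMatrix
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_mothur_relabund",
    "write_mothur_relabund",
    "read_mothur_shared",
    "read_oligotyping_matrix_percent",
    "write_oligotyping_matrix_percent",
    "read_sample_metadata",
    "write_network",
    "read_network",
]

NETWORK_FORMATS = ("edgelist", "graphml", "dot")


def _read_mothur_table(path: str | Path, kind: str) -> tuple[str, list[str], list[str], list[list[str]]]:
    """Shared parsing for .relabund/.shared: returns (label, taxa, samples, cells)."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "label" or header[1] != "Group" or header[2] != "numOtus":
        raise ValueError(
            f"{path}: not a mothur {kind} file (expected header 'label\\tGroup\\tnumOtus...')"
        )
    taxa = header[3:]
    if len(lines) < 2:
        raise ValueError(f"{path}: no samples")
    first_label: str | None = None
    samples: list[str] = []
    rows: list[list[str]] = []
    seen = set()
    skipped_blocks = False
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path} line {i}: expected {len(header)} fields, got {len(cells)}")
        label, group, num_otus = cells[0], cells[1], cells[2]
        if first_label is None:
            first_label = label
        elif label != first_label:
            skipped_blocks = True
            continue
        if group in seen:
            raise ValueError(f"{path} line {i}: duplicate sample {group!r}")
        seen.add(group)
        try:
            n = int(num_otus)
        except ValueError:
            raise ValueError(f"{path} line {i}: numOtus {num_otus!r} is not an integer") from None
        if n != len(taxa):
            raise ValueError(
                f"{path} line {i}: numOtus={n} inconsistent with {len(taxa)} taxon columns"
            )
        samples.append(group)
        rows.append(cells[3:])
    if skipped_blocks:
        logger.warning(
            "%s: multiple label blocks; reading only the first (label=%s)", path, first_label
        )
    if not samples:
        raise ValueError(f"{path}: no samples")
    return first_label or "", taxa, samples, rows


def _parse_cells(rows, taxa, samples, path, caster, what):
    data = {}
    for sample, cells in zip(samples, rows):
        parsed = []
        for taxon, cell in zip(taxa, cells):
            try:
                parsed.append(caster(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-{what} value {cell!r} at sample {sample!r}, column {taxon!r}"
                ) from None
        data[sample] = parsed
    return pd.DataFrame(data, index=taxa)


def read_mothur_relabund(path: str | Path) -> AbundanceMatrix:
    """Read a mothur ``.relabund`` file into an :class:`AbundanceMatrix`.

    The dialect already stores fractions; values pass through unscaled.
    Rows become samples, columns taxa; the returned matrix is transposed to
    taxa × samples.
    """
    label, taxa, samples, rows = _read_mothur_table(path, ".relabund")
    df = _parse_cells(rows, taxa, samples, path, float, "numeric")
    return AbundanceMatrix(df, label=label or None)


def write_mothur_relabund(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write the mothur ``.relabund`` dialect (fractions, full precision)."""
    path = Path(path)
    label = matrix.label or "0.03"
    with path.open("w") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *matrix.taxa]) + "\n")
        for sample in matrix.samples:
            vals = [repr(float(v)) for v in matrix.data[sample]]
            fh.write("\t".join([label, sample, str(matrix.n_taxa), *vals]) + "\n")


def read_mothur_shared(path: str | Path) -> CountMatrix:
    """Read a mothur ``.shared`` count table."""
    label, taxa, samples, rows = _read_mothur_table(path, ".shared")

    def to_int(cell: str) -> int:
        f = float(cell)
        if f != int(f):
            raise ValueError(cell)
        return int(f)

    df = _parse_cells(rows, taxa, samples, path, to_int, "integer")
    return CountMatrix(df, label=label or None)


def read_oligotyping_matrix_percent(path: str | Path) -> AbundanceMatrix:
    """Read an oligotyping ``matrix_percents.txt`` file.

    Cells are percentages in [0, 100]; they are divided by 100 so the
    returned matrix holds fractions like every other input.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "samples":
        raise ValueError(f"{path}: expected header starting with 'samples'")
    taxa = header[1:]
    samples: list[str] = []
    rows: list[list[str]] = []
    seen = set()
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path} line {i}: expected {len(header)} fields, got {len(cells)}")
        if cells[0] in seen:
            raise ValueError(f"{path} line {i}: duplicate sample {cells[0]!r}")
        seen.add(cells[0])
        samples.append(cells[0])
        rows.append(cells[1:])
    df = _parse_cells(rows, taxa, samples, path, float, "numeric")
    bad = df[(df < 0) | (df > 100)].stack()
    if not bad.empty:
        taxon, sample = bad.index[0]
        raise ValueError(
            f"{path}: percentage {bad.iloc[0]} outside [0, 100] at "
            f"sample {sample!r}, column {taxon!r}"
        )
    return AbundanceMatrix(df / 100.0)


def write_oligotyping_matrix_percent(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write the oligotyping percent dialect (fractions × 100, 6 decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["samples", *matrix.taxa]) + "\n")
        for sample in matrix.samples:
            vals = [f"{100.0 * v:.6f}" for v in matrix.data[sample]]
            fh.write("\t".join([sample, *vals]) + "\n")


def read_sample_metadata(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→region table (header optional)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    for i, line in enumerate(lines, start=1):
        cells = line.split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path} line {i}: expected 2 tab-separated fields")
        if i == 1 and cells[0].lower() == "sample":
            continue
        sample, region = cells
        if sample in mapping:
            raise ValueError(f"{path} line {i}: duplicate sample {sample!r}")
        mapping[sample] = region
    return mapping


# -- network export --------------------------------------------------------

def _sorted_graph(network: InteractionNetwork) -> nx.MultiDiGraph:
    """Rebuild the graph with sorted node/edge insertion for byte-stable output."""
    g = nx.MultiDiGraph()
    for node in network.nodes():
        attrs = network.node_attrs(node)
        g.add_node(node, **attrs)
    for e in network.edges():
        g.add_edge(
            e.source, e.target, key=e.sign, sign=e.sign, weight=e.weight, n_triplets=e.n_triplets
        )
    return g


def write_network(network: InteractionNetwork, format: str, path: str | Path) -> None:
    """Export a network as a tab-delimited edge list, GraphML, or DOT.

    Row/element order is deterministic (sorted by source, target, sign), so
    two writes of the same network are byte-identical.
    """
    path = Path(path)
    if format == "edgelist":
        with path.open("w") as fh:
            fh.write("source\ttarget\tsign\tweight\tn_triplets\n")
            for e in network.edges():
                fh.write(f"{e.source}\t{e.target}\t{e.sign}\t{e.weight:.6f}\t{e.n_triplets}\n")
    elif format == "graphml":
        nx.write_graphml(_sorted_graph(network), path, named_key_ids=True)
    elif format == "dot":
        with path.open("w") as fh:
            fh.write("digraph rmn {\n")
            for node in network.nodes():
                attrs = network.node_attrs(node)
                parts = [f'label="{node}"']
                if "category" in attrs:
                    parts.append(f'category="{attrs["category"]}"')
                if "max_abundance" in attrs:
                    parts.append(f'max_abundance="{attrs["max_abundance"]:.6g}"')
                fh.write(f'  "{node}" [{", ".join(parts)}];\n')
            for e in network.edges():
                fh.write(
                    f'  "{e.source}" -> "{e.target}" '
                    f'[sign="{e.sign}", weight="{e.weight:.6f}", n_triplets="{e.n_triplets}"];\n'
                )
            fh.write("}\n")
    else:
        raise ValueError(f"unknown network format {format!r}; valid: {NETWORK_FORMATS}")


def read_network(path: str | Path, format: str = "graphml") -> InteractionNetwork:
    """Read a network back from GraphML or an edge-list TSV."""
    path = Path(path)
    net = InteractionNetwork()
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for node, attrs in g.nodes(data=True):
            net.add_node(
                node,
                category=attrs.get("category"),
                max_abundance=attrs.get("max_abundance"),
            )
        for u, v, d in g.edges(data=True):
            net.add_interaction(u, v, d["sign"], float(d["weight"]))
            net.graph[u][v][d["sign"]]["n_triplets"] = int(d["n_triplets"])
    elif format == "edgelist":
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            net.add_interaction(row.source, row.target, row.sign, float(row.weight))
            net.graph[row.source][row.target][row.sign]["n_triplets"] = int(row.n_triplets)
    else:
        raise ValueError(f"unknown network format {format!r}; valid: ('edgelist', 'graphml')")
    return net
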