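"""Undirected protein-protein interaction networks.

Nodes are gene symbols (case-preserved, matched exactly); edges are
unordered, unweighted interaction records.  Self-loops and duplicate
evidence rows are collapsed on ingest: the downstream topology features
(clustering coefficient, neighbor counts) are defined on simple graphs
and no edge-weighting scheme is used.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    """Base class for network construction/lookup failures."""


class NetworkFormatError(NetworkError):
    """Input file is missing, malformed, or lacks required columns."""


class EmptyNetworkError(NetworkError):
    """No edges survived filtering."""


class UnknownGeneError(KeyError):
    """A requested gene symbol is not a node of the network."""


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PPINetwork:
    """Simple undirected graph over gene symbols.

    Invariants: no self-loops, no parallel edges, every edge endpoint is a
    node; isolated nodes are permitted.  ``species_tag`` labels the organism
    (human and mouse networks are handled strictly separately).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    species_tag: str = "unspecified"

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        species_tag: str = "unspecified",
        nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build a network, dropping self-loops and duplicate rows.

        ``nodes`` may add isolated nodes beyond the edge endpoints.
        Dropped-row counts are logged, not raised.
        """
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            u, v = _canonical(a, b)
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        g.add_nodes_from(nodes)
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop row(s) and %d duplicate row(s)", n_self, n_dup
            )
        return cls(graph=g, species_tag=species_tag)

    # -- properties ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical(a, b) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        self._require(gene)
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        self._require(gene)
        return int(self.graph.degree[gene])

    def _require(self, gene: str) -> None:
        if not self.graph.has_node(gene):
            raise UnknownGeneError(f"gene {gene!r} is not in the network")

    # -- serialization ------------------------------------------------

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def write_edge_list(self, path: str | Path) -> None:
        """Canonical sorted two-column TSV; isolated nodes are not preserved."""
        with open(path, "w") as fh:
            for a, b in self.sorted_edges():
                fh.write(f"{a}\t{b}\n")

    def write_sif(self, path: str | Path, interaction: str = "pp") -> None:
        with open(path, "w") as fh:
            for a, b in self.sorted_edges():
                fh.write(f"{a}\t{interaction}\t{b}\n")


def read_edge_list(path: str | Path, species_tag: str = "unspecified") -> PPINetwork:
    """Read a tab- or comma-separated edge list (first two columns = interactors).

    Self-loops and duplicate rows are silently dropped (counts logged).

    Raises
    ------
    NetworkFormatError
        Missing file or a row with fewer than 2 columns.
    EmptyNetworkError
        No edges remain after filtering.
    """
    path = Path(path)
    if not path.is_file():
        raise NetworkFormatError(f"edge-list file not found: {path}")
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        for i, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise NetworkFormatError(
                    f"{path}:{i}: expected >=2 columns, got {len(row)}"
                )
            pairs.append((row[0].strip(), row[1].strip()))
    net = PPINetwork.from_edges(pairs, species_tag=species_tag)
    if net.n_edges == 0:
        raise EmptyNetworkError(f"empty network after filtering: {path}")
    return net


_BIOGRID_COLS = {
    "sym_a": "Official Symbol Interactor A",
    "sym_b": "Official Symbol Interactor B",
    "tax_a": "Organism ID Interactor A",
    "tax_b": "Organism ID Interactor B",
}
_BIOGRID_SYSTEM_TYPE = "Experimental System Type"


def read_biogrid_tab3(
    path: str | Path,
    organism_taxid: int,
    species_tag: str | None = None,
    physical_only: bool = False,
) -> PPINetwork:
    """Read a BioGRID TAB3 flat file, keeping rows where BOTH interactors
    match ``organism_taxid``.

    ``physical_only`` restricts to rows whose "Experimental System Type"
    column equals "physical", when that column is present; by default no
    evidence-type filter is applied.
    """
    path = Path(path)
    if not path.is_file():
        raise NetworkFormatError(f"BioGRID file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise NetworkFormatError(f"BioGRID file is empty: {path}") from None
        header = [h.lstrip("#").strip() for h in header]
        idx = {}
        for key, col in _BIOGRID_COLS.items():
            if col not in header:
                raise NetworkFormatError(
                    f"BioGRID header missing required column {col!r}"
                )
            idx[key] = header.index(col)
        sys_idx = header.index(_BIOGRID_SYSTEM_TYPE) if _BIOGRID_SYSTEM_TYPE in header else None
        if physical_only and sys_idx is None:
            logger.warning(
                "physical_only requested but %r column absent; no filter applied",
                _BIOGRID_SYSTEM_TYPE,
            )
        pairs: list[tuple[str, str]] = []
        taxid = str(organism_taxid)
        for row in reader:
            if not row:
                continue
            if row[idx["tax_a"]].strip() != taxid or row[idx["tax_b"]].strip() != taxid:
                continue
            if physical_only and sys_idx is not None and row[sys_idx].strip() != "physical":
                continue
            pairs.append((row[idx["sym_a"]].strip(), row[idx["sym_b"]].strip()))
    if not pairs:
        raise EmptyNetworkError(
            f"zero rows pass the taxid {organism_taxid} filter: {path}"
        )
    net = PPINetwork.from_edges(
        pairs, species_tag=species_tag if species_tag is not None else str(organism_taxid)
    )
    if net.n_edges == 0:
        raise EmptyNetworkError(f"empty network after filtering: {path}")
    return net


def connected_component_of(net: PPINetwork, gene: str) -> set[str]:
    """All nodes reachable from ``gene``, including ``gene`` itself."""
    net._require(gene)
    return set(nx.node_connected_component(net.graph, gene))


def read_positive_genes(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comments and blank lines ignored."""
    path = Path(path)
    if not path.is_file():
        raise NetworkFormatError(f"gene-list file not found: {path}")
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return genes


def export_json(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "species_tag": net.species_tag,
                "nodes": sorted(net.nodes),
                "edges": [list(e) for e in net.sorted_edges()],
            },
            fh,
            indent=1,
        )


def check_same_species(*nets_or_tags: "PPINetwork | str") -> str:
    """Raise if objects carry different species tags (human/mouse never mix)."""
    tags = {
        x.species_tag if isinstance(x, PPINetwork) else x for x in nets_or_tags
    }
    if len(tags) > 1:
        raise NetworkError(f"species tags differ: {sorted(tags)}")
    return next(iter(tags)) if tags else "unspecified"
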