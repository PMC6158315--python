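"""Reading expression/phenotype tables and writing networks and reports.

File conventions follow the GeneNetwork export style: tab-delimited text
with one header row and one label column, ``NA`` (or an empty cell) for
missing values.  Networks go out as a sorted undirected edge list or as
GraphML with a double-typed ``weight`` edge attribute and a string
``node_class`` node attribute.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateTraitError,
    DomainError,
    DuplicateLabelError,
    ParseError,
)
from .graph import Network

log = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "")

#: minimum non-missing strains a trait needs to be correlatable at all
MIN_TRAIT_OBS = 3


@dataclass
class ExpressionMatrix:
    """Transcript abundance per strain, transcripts × strains.

    ``values`` is a float matrix with NaN marking missing cells.
    """

    transcript_ids: list[str]
    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.transcript_ids, "transcript")
        _check_unique(self.strain_ids, "strain")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.strain_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.strain_ids)} strains"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.strain_ids
        )


@dataclass
class PhenotypeTable:
    """Trait measurements per strain, traits × strains (NaN = not phenotyped)."""

    trait_ids: list[str]
    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.trait_ids, "trait")
        _check_unique(self.strain_ids, "strain")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.trait_ids), len(self.strain_ids)):
            raise ParseError(
                f"table shape {self.values.shape} does not match "
                f"{len(self.trait_ids)} traits x {len(self.strain_ids)} strains"
            )
        if not self.trait_ids:
            raise DegenerateTraitError("phenotype table has no traits")

    def check_traits(self, min_obs: int = MIN_TRAIT_OBS) -> None:
        """Reject traits with too few non-missing strains to correlate.

        Applied when a table is *read*; later strain-subset restrictions
        (alignment) may legitimately shrink counts further — such traits
        simply produce undefined correlations downstream.
        """
        for trait, n in self.non_missing_counts().items():
            if n < min_obs:
                raise DegenerateTraitError(
                    f"trait {trait!r} has only {n} non-missing strains "
                    f"(minimum {min_obs})"
                )

    def non_missing_counts(self) -> dict[str, int]:
        return {
            t: int(np.sum(np.isfinite(row)))
            for t, row in zip(self.trait_ids, self.values)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.trait_ids, columns=self.strain_ids)


@dataclass
class AlignedDataset:
    """Expression and phenotype restricted to their shared strains.

    Strain order is lexicographic so every downstream statistic is
    independent of input column order.
    """

    shared_strain_ids: list[str]
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    trait_n_obs: dict[str, int] = field(default_factory=dict)

    @property
    def trait_ids(self) -> list[str]:
        return self.phenotypes.trait_ids

    @property
    def transcript_ids(self) -> list[str]:
        return self.expression.transcript_ids


def _check_unique(labels: list[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateLabelError(f"duplicate {kind} label {lab!r}")
        seen.add(lab)


def _read_labeled_table(path) -> pd.DataFrame:
    """Tab-delimited table with a header row and a label column; NA/empty = missing."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column")
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        skip_blank_lines=True,
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    dupes = frame.index[frame.index.duplicated()]
    if len(dupes):
        raise DuplicateLabelError(f"duplicate row label {dupes[0]!r} in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    # cells that failed numeric conversion but were not declared missing
    bad = numeric.isna() & frame.notna() & ~frame.isin(MISSING_TOKENS)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {frame.iloc[i, j]!r} at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r} in {path}"
        )
    return numeric


def read_expression_matrix(path, dialect: str = "rows=transcripts") -> ExpressionMatrix:
    """Read an expression table; returns canonical transcripts × strains.

    ``dialect`` names which axis the file's rows carry; a transposed file
    read with ``rows=strains`` yields the identical canonical matrix.
    """
    if dialect not in ("rows=transcripts", "rows=strains"):
        raise DomainError(f"unknown dialect {dialect!r}")
    frame = _read_labeled_table(path)
    if dialect == "rows=strains":
        frame = frame.T
    return ExpressionMatrix(
        transcript_ids=list(frame.index),
        strain_ids=list(frame.columns),
        values=frame.to_numpy(),
    )


def read_phenotype_table(path) -> PhenotypeTable:
    """Read a phenotype table (strains as rows, traits as columns — the
    GeneNetwork trait-export convention) into the traits × strains type."""
    frame = _read_labeled_table(path).T  # -> traits x strains
    table = PhenotypeTable(
        trait_ids=list(frame.index),
        strain_ids=list(frame.columns),
        values=frame.to_numpy(),
    )
    table.check_traits()
    return table


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    _write_table(expr.to_frame(), path, index_label="transcript_id")


def write_phenotype_table(pheno: PhenotypeTable, path) -> None:
    # written strains x traits, mirroring the read convention
    _write_table(pheno.to_frame().T, path, index_label="strain_id")


def _write_table(frame: pd.DataFrame, path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", index_label=index_label, float_format="%g")


def align_strains(expr: ExpressionMatrix, pheno: PhenotypeTable) -> AlignedDataset:
    """Restrict both tables to the lexically sorted strain intersection.

    Strains present on only one side are dropped and logged.  The study
    design this serves pairs a phenotype panel (31 strains) with a larger
    expression panel (69 strains), so dropping is the normal case.
    """
    expr_set = set(expr.strain_ids)
    pheno_set = set(pheno.strain_ids)
    shared = sorted(expr_set & pheno_set)
    if not shared:
        raise AlignmentError("expression and phenotype tables share no strains")
    dropped_expr = sorted(expr_set - pheno_set)
    dropped_pheno = sorted(pheno_set - expr_set)
    if dropped_expr:
        log.info("align_strains: dropped %d expression-only strains: %s",
                 len(dropped_expr), ", ".join(dropped_expr))
    if dropped_pheno:
        log.info("align_strains: dropped %d phenotype-only strains: %s",
                 len(dropped_pheno), ", ".join(dropped_pheno))
    e_idx = [expr.strain_ids.index(s) for s in shared]
    p_idx = [pheno.strain_ids.index(s) for s in shared]
    expr_sub = ExpressionMatrix(
        transcript_ids=list(expr.transcript_ids),
        strain_ids=shared,
        values=expr.values[:, e_idx],
    )
    pheno_sub = PhenotypeTable(
        trait_ids=list(pheno.trait_ids),
        strain_ids=shared,
        values=pheno.values[:, p_idx],
    )
    return AlignedDataset(
        shared_strain_ids=shared,
        expression=expr_sub,
        phenotypes=pheno_sub,
        trait_n_obs=pheno_sub.non_missing_counts(),
    )


# ---------------------------------------------------------------------------
# network serialization

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_network(net: Network, path, format: str = "edge_list_tsv") -> None:
    """Write a network as a sorted TSV edge list or as GraphML.

    The edge list has columns node_a, node_b, weight with node_a < node_b
    lexically and the weight printed to six decimal places, so identical
    networks produce byte-identical files.
    """
    if format == "edge_list_tsv":
        with open(path, "w") as handle:
            handle.write("node_a\tnode_b\tweight\n")
            for u, v, w in net.edges():
                handle.write(f"{u}\t{v}\t{w:.6f}\n")
    elif format == "graphml":
        _write_graphml(net, path)
    else:
        raise DomainError(f"unknown network format {format!r}")


def _write_graphml(net: Network, path) -> None:
    root = ET.Element("graphml", xmlns=GRAPHML_NS)
    ET.SubElement(root, "key", id="d0", **{
        "for": "node", "attr.name": "node_class", "attr.type": "string"})
    ET.SubElement(root, "key", id="d1", **{
        "for": "edge", "attr.name": "weight", "attr.type": "double"})
    graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
    for node in net.nodes():
        el = ET.SubElement(graph, "node", id=node)
        data = ET.SubElement(el, "data", key="d0")
        data.text = net.node_class(node)
    for u, v, w in net.edges():
        el = ET.SubElement(graph, "edge", source=u, target=v)
        data = ET.SubElement(el, "data", key="d1")
        data.text = repr(float(w))
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_network(path, format: str = "edge_list_tsv") -> Network:
    """Read a network written by :func:`write_network`."""
    if format == "edge_list_tsv":
        net = Network()
        with open(path) as handle:
            header = handle.readline()
            if not header.startswith("node_a"):
                raise ParseError(f"{path}: missing edge-list header")
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    u, v, w = line.split("\t")
                except ValueError:
                    raise ParseError(f"{path}: malformed edge row {line!r}") from None
                net.add_edge(u, v, float(w))
        return net
    if format == "graphml":
        return _read_graphml(path)
    raise DomainError(f"unknown network format {format!r}")


def _read_graphml(path) -> Network:
    ns = {"g": GRAPHML_NS}
    tree = ET.parse(path)
    root = tree.getroot()
    keymap = {}
    for key in root.findall("g:key", ns):
        keymap[(key.get("for"), key.get("attr.name"))] = key.get("id")
    class_key = keymap.get(("node", "node_class"))
    weight_key = keymap.get(("edge", "weight"))
    net = Network()
    graph = root.find("g:graph", ns)
    if graph is None:
        raise ParseError(f"{path}: no <graph> element")
    for el in graph.findall("g:node", ns):
        node_class = "transcript"
        for data in el.findall("g:data", ns):
            if data.get("key") == class_key and data.text:
                node_class = data.text
        net.add_node(el.get("id"), node_class)
    for el in graph.findall("g:edge", ns):
        weight = 1.0
        for data in el.findall("g:data", ns):
            if data.get("key") == weight_key and data.text:
                weight = float(data.text)
        net.add_edge(el.get("source"), el.get("target"), weight)
    return net
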