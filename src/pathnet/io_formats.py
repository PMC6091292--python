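"""Domain containers and readers/writers for the standard formats the pipeline touches.

Every downstream module consumes only the in-memory types defined here:
expression matrices (TSV), phenotype labels (TSV), gene sets (GMT), PPI
edge lists (TSV), Gene Ontology structure (OBO) and gene annotations
(GAF 2.x).  Readers validate hard invariants (unique identifiers, finite
numeric values, acyclic ontology) and fail loudly rather than imputing.

Gene identifiers are plain case-sensitive strings throughout; no alias
resolution or probe collapsing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: GAF aspect code -> ontology namespace
ASPECT_TO_NAMESPACE = {"P": "BP", "F": "MF", "C": "CC"}

#: OBO namespace field -> short namespace
OBO_NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

NAMESPACES = ("BP", "MF", "CC")


class FormatError(ValueError):
    """A file violated the format contract (hard error, no repair)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (assumed log-scale) expression intensities."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if self.values.size == 0:
            raise FormatError("empty expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression value")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def subset_genes(self, genes: list[str]) -> np.ndarray:
        """Rows for ``genes`` in the given order (genes must exist)."""
        idx = [self._gene_index[g] for g in genes]
        return self.values[idx]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeVector:
    """Binary phenotype per sample: 1 = tumor/case, 0 = normal/control."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample id {_first_duplicate(self.sample_ids)!r}")
        if self.labels.shape != (len(self.sample_ids),):
            raise FormatError("labels length does not match sample ids")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise FormatError("phenotype labels must be 0 or 1")
        if len(set(self.labels.tolist())) < 2:
            raise FormatError("both phenotype classes must be present")

    def aligned_to(self, expr: ExpressionMatrix) -> "PhenotypeVector":
        """Reorder to the sample order of ``expr``; error on mismatch."""
        if set(self.sample_ids) != set(expr.sample_ids):
            raise FormatError("phenotype sample ids do not match expression matrix")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in expr.sample_ids]
        return PhenotypeVector(list(expr.sample_ids), self.labels[order])


@dataclass
class PathwayCollection:
    """Ordered, named gene sets (as from an MSigDB-style GMT file)."""

    entries: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.entries.items():
            if not members:
                raise FormatError(f"pathway {name!r} has no members")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.entries[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self.entries == other.entries


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction edges over gene identifiers."""

    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class OntologyDAG:
    """Gene Ontology structure: child -> parent edges labelled is_a / part_of."""

    graph: nx.DiGraph  # directed child -> parent, edge attr "relation"
    namespace: dict[str, str]  # term -> BP / MF / CC
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise FormatError("ontology graph contains a cycle")

    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of ``term``."""
        return [(p, self.graph.edges[term, p]["relation"]) for p in self.graph.successors(term)]

    def __contains__(self, term: str) -> bool:
        return term in self.graph


@dataclass
class AnnotationMap:
    """Per-namespace gene -> GO term annotations (cleaned: no NOT, no obsolete)."""

    by_namespace: dict[str, dict[str, set[str]]]

    def terms_for(self, gene: str, namespace: str) -> set[str]:
        return self.by_namespace.get(namespace, {}).get(gene, set())

    def annotated_namespaces(self, gene: str) -> list[str]:
        return [ns for ns in NAMESPACES if self.terms_for(gene, ns)]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV: first column gene ids, header row sample ids.

    Values are used bit-exactly as parsed; any non-numeric cell (including
    ``NA``) is a hard error — no imputation is attempted.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    genes = [str(g) for g in df.index]
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate gene id {_first_duplicate(genes)!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        bad = df.map(_is_not_number)
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at gene {genes[r]!r}, "
            f"sample {df.columns[c]!r}"
        ) from None
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise FormatError(f"{path}: non-finite value at gene {genes[r]!r}, sample {df.columns[c]!r}")
    return ExpressionMatrix(genes, [str(s) for s in df.columns], values)


def read_phenotype(path) -> PhenotypeVector:
    """Read a two-column TSV: sample_id TAB label (1 = tumor, 0 = normal)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    # tolerate a header line
    if df.iloc[0]["label"] not in ("0", "1"):
        df = df.iloc[1:]
    try:
        labels = df["label"].astype(int).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer phenotype label") from exc
    return PhenotypeVector([str(s) for s in df["sample"]], labels)


def read_gene_sets(path) -> PathwayCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene ...

    File order is preserved; duplicate genes within one line are dropped
    (first occurrence kept); a duplicated pathway name is a hard error.
    """
    entries: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in entries:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            members = tuple(dict.fromkeys(g for g in genes if g))
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            entries[name] = members
            descriptions[name] = desc
    if not entries:
        raise FormatError(f"{path}: empty GMT file")
    return PathwayCollection(entries, descriptions)


def read_ppi(path, skip_header: bool = False) -> PPINetwork:
    """Read an undirected edge-list TSV (two id columns; extras ignored).

    Duplicate edges and reversed orientations collapse to one edge;
    self-loops are dropped with a logged count.  A literal header row is
    not auto-detected — pass ``skip_header=True`` if one is present.
    """
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line has fewer than 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                self_loops += 1
                continue
            edges.add((a, b) if a <= b else (b, a))
    if self_loops:
        logger.info("read_ppi: dropped %d self-loop(s)", self_loops)
    if not edges:
        raise FormatError(f"{path}: no edges")
    return PPINetwork(edges)


def read_ontology(path) -> OntologyDAG:
    """Read an OBO 1.2/1.4 file into an OntologyDAG (is_a and part_of edges).

    obonet orients edges child -> parent already; obsolete terms are kept in
    the term list but flagged, and a cyclic ontology is a hard error.
    """
    multi = obonet.read_obo(path)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    obsolete: set[str] = set()
    for term, data in multi.nodes(data=True):
        ns = OBO_NAMESPACES.get(data.get("namespace", ""), data.get("namespace"))
        graph.add_node(term)
        if ns:
            namespace[term] = ns
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term)
    for child, parent, key in multi.edges(keys=True):
        if key in ("is_a", "part_of"):
            graph.add_edge(child, parent, relation=key)
    return OntologyDAG(graph, namespace, obsolete)


def read_annotations(path, dag: OntologyDAG, exclude_iea: bool = False) -> AnnotationMap:
    """Read a GAF 2.x file against ``dag``.

    Rows with qualifier NOT are excluded; annotations to unknown or obsolete
    terms are dropped with a logged count; aspects map P->BP, F->MF, C->CC.
    Evidence codes are not filtered unless ``exclude_iea`` is set.
    """
    by_ns: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
    dropped_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise FormatError(f"{path}:{lineno}: GAF row has fewer than 15 columns")
            gene, qualifier, term, evidence, aspect = cols[1], cols[3], cols[4], cols[6], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if exclude_iea and evidence == "IEA":
                continue
            if term not in dag or term in dag.obsolete:
                dropped_unknown += 1
                continue
            ns = ASPECT_TO_NAMESPACE.get(aspect)
            if ns is None:
                raise FormatError(f"{path}:{lineno}: unknown aspect {aspect!r}")
            by_ns[ns].setdefault(gene, set()).add(term)
    if dropped_unknown:
        logger.info("read_annotations: dropped %d annotation(s) to unknown/obsolete terms", dropped_unknown)
    return AnnotationMap(by_ns)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="gene")


def write_phenotype(pheno: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        for s, l in zip(pheno.sample_ids, pheno.labels):
            fh.write(f"{s}\t{int(l)}\n")


def write_gene_sets(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.entries.items():
            desc = collection.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_ppi(ppi: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


def write_rank_table(result, path) -> None:
    """Serialize a RankResult as a TSV: rank, pathway, counts, MI, r, p-value.

    Rows are sorted by descending GeneRank score r, ties broken by
    descending MI then lexicographic pathway name.
    """
    header = ["rank", "pathway", "n_candidate_genes", "pathway_size", "n_deg_in_pathway", "mi", "r", "p_value"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rank, name in enumerate(result.ordering, 1):
            i = result.index[name]
            fh.write(
                "\t".join(
                    [
                        str(rank),
                        name,
                        str(result.n_candidates[i]),
                        str(result.pathway_sizes[i]),
                        str(result.n_deg_in_pathway[i]),
                        f"{result.ex_raw[i]:.10g}",
                        f"{result.r[i]:.10g}",
                        f"{result.pvalues[i]:.6g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _is_not_number(x) -> bool:
    try:
        float(x)
        return False
    except (TypeError, ValueError):
        return True
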