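"""Synthetic case/control study generator with planted disease pathways.

Emulates the statistical structure of a two-group microarray study joined
to a PPI network, pathway gene sets and GO annotations:

* expression is standard normal per gene (log-like scale, already
  normalized), with a mean shift of ``effect_size`` SDs added to planted
  pathway member genes in tumor samples;
* PPI edges are Bernoulli, enriched within pathways over background;
* each namespace of the ontology is a small rooted DAG, and every pathway
  owns a clique of "theme" leaf terms annotated to most of its members, so
  genes of one pathway are semantically close under the Wang measure;
* the planted truth (pathway names + genes) is carried alongside.

Everything is deterministic under the spec seed.  Probe-level noise,
batch effects and platform merging are deliberately not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import io_formats as iof
from .io_formats import (
    AnnotationMap,
    ExpressionMatrix,
    OntologyDAG,
    PathwayCollection,
    PhenotypeVector,
    PPINetwork,
)

_NS_LONG = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}


@dataclass
class SyntheticSpec:
    """Generator conditions for one synthetic study."""

    n_genes: int = 2000
    n_normal: int = 50
    n_tumor: int = 50
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    n_planted: int = 3
    effect_size: float = 1.5  # mean shift in SD units, tumor samples of planted genes
    ppi_p_within: float = 0.3
    ppi_p_background: float = 0.002
    ontology_depth: int = 4
    terms_per_pathway_theme: int = 3
    annotation_coverage: float = 0.9  # fraction of pathway members carrying theme terms
    background_annotation_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_pathways:
            raise ValueError("cannot plant more pathways than exist")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        for p in (self.ppi_p_within, self.ppi_p_background, self.background_annotation_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway size exceeds gene universe")
        if self.ontology_depth < 3:
            raise ValueError("ontology depth must be at least 3")


@dataclass
class SyntheticBundle:
    """A complete synthetic study plus its planted ground truth."""

    expression: ExpressionMatrix
    phenotype: PhenotypeVector
    pathways: PathwayCollection
    ppi: PPINetwork
    ontology: OntologyDAG
    annotations: AnnotationMap
    truth_pathways: list[str]
    truth_genes: list[str]


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw one complete bundle under ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = [f"N{i:03d}" for i in range(spec.n_normal)] + [
        f"T{i:03d}" for i in range(spec.n_tumor)
    ]
    labels = np.array([0] * spec.n_normal + [1] * spec.n_tumor)

    pathways = _draw_pathways(spec, genes, rng)
    planted = list(pathways.names[: spec.n_planted])
    planted_genes = sorted({g for name in planted for g in pathways[name]})

    values = rng.standard_normal((spec.n_genes, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_rows = [gene_pos[g] for g in planted_genes]
    values[np.ix_(planted_rows, np.where(labels == 1)[0])] += spec.effect_size

    expr = ExpressionMatrix(genes, samples, values)
    pheno = PhenotypeVector(list(samples), labels)
    ppi = _draw_ppi(spec, genes, pathways, rng)
    ontology, theme_terms = _draw_ontology(spec, pathways.names, rng)
    annotations = _draw_annotations(spec, pathways, genes, theme_terms, rng)

    return SyntheticBundle(
        expr, pheno, pathways, ppi, ontology, annotations, planted, planted_genes
    )


def export(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write the bundle in the pipeline's standard input formats.

    Truth goes to a separate JSON; everything else round-trips through the
    io_formats readers to an equal in-memory bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "phenotype": out / "phenotype.tsv",
        "pathways": out / "pathways.gmt",
        "ppi": out / "ppi.tsv",
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.gaf",
        "truth": out / "truth.json",
    }
    iof.write_expression(bundle.expression, paths["expression"])
    iof.write_phenotype(bundle.phenotype, paths["phenotype"])
    iof.write_gene_sets(bundle.pathways, paths["pathways"])
    iof.write_ppi(bundle.ppi, paths["ppi"])
    _write_obo(bundle.ontology, paths["ontology"])
    _write_gaf(bundle.annotations, paths["annotations"])
    paths["truth"].write_text(
        json.dumps(
            {"planted_pathways": bundle.truth_pathways, "planted_genes": bundle.truth_genes},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _draw_pathways(spec: SyntheticSpec, genes: list[str], rng) -> PathwayCollection:
    """Planted pathways are mutually disjoint; background pathways draw from
    the non-planted pool (bounded overlap: background sets may overlap each
    other but never the planted signal)."""
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    planted_total = int(sizes[: spec.n_planted].sum())
    if planted_total > spec.n_genes:
        raise ValueError("planted pathways exceed the gene universe")
    planted_pool = rng.choice(len(genes), size=planted_total, replace=False)
    background_pool = np.setdiff1d(np.arange(len(genes)), planted_pool)

    entries: dict[str, tuple[str, ...]] = {}
    offset = 0
    for i in range(spec.n_planted):
        take = planted_pool[offset : offset + sizes[i]]
        offset += sizes[i]
        entries[f"PLANTED_{i + 1:02d}"] = tuple(genes[j] for j in np.sort(take))
    for i in range(spec.n_planted, spec.n_pathways):
        take = rng.choice(background_pool, size=sizes[i], replace=False)
        entries[f"PATHWAY_{i + 1:03d}"] = tuple(genes[j] for j in np.sort(take))
    return PathwayCollection(entries, {name: "synthetic" for name in entries})


def _draw_ppi(spec: SyntheticSpec, genes, pathways: PathwayCollection, rng) -> PPINetwork:
    edges: set[tuple[str, str]] = set()
    for members in pathways.entries.values():
        ms = list(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if rng.random() < spec.ppi_p_within:
                    a, b = ms[i], ms[j]
                    edges.add((a, b) if a <= b else (b, a))
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    count = rng.binomial(n_pairs, spec.ppi_p_background)
    if count:
        iu, ju = np.triu_indices(n, 1)
        pick = rng.choice(n_pairs, size=count, replace=False)
        for i, j in zip(iu[pick], ju[pick]):
            edges.add((genes[i], genes[j]))
    return PPINetwork(edges)


def _draw_ontology(spec: SyntheticSpec, pathway_names, rng):
    """One rooted DAG per namespace: root -> branches -> theme parents ->
    theme leaf terms (one theme parent per pathway).  Mostly is_a edges, with
    one part_of edge per theme group for relation diversity."""
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    theme_terms: dict[str, dict[str, list[str]]] = {ns: {} for ns in iof.NAMESPACES}
    counter = 1

    def new_term(ns: str) -> str:
        nonlocal counter
        term = f"GO:{counter:07d}"
        counter += 1
        graph.add_node(term)
        namespace[term] = ns
        return term

    n_branch = 5
    for ns in iof.NAMESPACES:
        root = new_term(ns)
        level = [root]
        # intermediate branch levels between root and theme parents
        for _ in range(spec.ontology_depth - 3):
            nxt = []
            for _ in range(n_branch):
                t = new_term(ns)
                graph.add_edge(t, level[rng.integers(len(level))], relation="is_a")
                nxt.append(t)
            level = nxt
        for name in pathway_names:
            parent = new_term(ns)
            graph.add_edge(parent, level[rng.integers(len(level))], relation="is_a")
            terms = []
            for k in range(spec.terms_per_pathway_theme):
                t = new_term(ns)
                rel = "part_of" if k == spec.terms_per_pathway_theme - 1 else "is_a"
                graph.add_edge(t, parent, relation=rel)
                terms.append(t)
            theme_terms[ns][name] = terms
    return OntologyDAG(graph, namespace), theme_terms


def _draw_annotations(spec, pathways: PathwayCollection, genes, theme_terms, rng) -> AnnotationMap:
    by_ns: dict[str, dict[str, set[str]]] = {ns: {} for ns in iof.NAMESPACES}
    for ns in iof.NAMESPACES:
        for name, members in pathways.entries.items():
            terms = theme_terms[ns][name]
            members = list(members)
            n_cov = math.ceil(spec.annotation_coverage * len(members))
            covered = rng.permutation(len(members))[:n_cov]
            for idx in covered:
                gene = members[idx]
                k = int(rng.integers(1, len(terms) + 1))
                chosen = rng.choice(len(terms), size=k, replace=False)
                by_ns[ns].setdefault(gene, set()).update(terms[c] for c in chosen)
        # background noise annotations over the whole universe
        all_terms = [t for ts in theme_terms[ns].values() for t in ts]
        hits = np.where(rng.random(len(genes)) < spec.background_annotation_p)[0]
        for idx in hits:
            by_ns[ns].setdefault(genes[idx], set()).add(
                all_terms[int(rng.integers(len(all_terms)))]
            )
    return AnnotationMap(by_ns)


def _write_obo(dag: OntologyDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in dag.terms():
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = dag.namespace.get(term)
            if ns:
                fh.write(f"namespace: {_NS_LONG[ns]}\n")
            if term in dag.obsolete:
                fh.write("is_obsolete: true\n")
            for parent, rel in dag.parents(term):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def _write_gaf(ann: AnnotationMap, path) -> None:
    ns_to_aspect = {v: k for k, v in iof.ASPECT_TO_NAMESPACE.items()}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ns in iof.NAMESPACES:
            aspect = ns_to_aspect[ns]
            for gene in sorted(ann.by_namespace.get(ns, {})):
                for term in sorted(ann.by_namespace[ns][gene]):
                    cols = [
                        "SYN",  # DB
                        gene,  # DB object id
                        gene,  # symbol
                        "enables",  # qualifier
                        term,  # GO id
                        "SYN:0001",  # reference
                        "IEA",  # evidence
                        "",  # with/from
                        aspect,  # aspect
                        gene,  # name
                        "",  # synonym
                        "protein",  # type
                        "taxon:9606",  # taxon
                        "20180730",  # date
                        "SYN",  # assigned by
                        "",  # extension
                        "",  # form id
                    ]
                    fh.write("\t".join(cols) + "\n")
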