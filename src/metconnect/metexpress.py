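"""Key cancer enzyme prediction from co-expression modules overlaid with a
metabolic enzyme-link network.

The procedure: (1) build a gene co-expression network by thresholding absolute
Pearson correlation; (2) partition it into modules by seeded modularity
maximization; (3) quantify each module's cancer-specificity as the ROC AUC of
its per-sample median expression for classifying cancer vs normal samples;
(4) link two enzyme-coding genes whenever a product of a reaction catalyzed by
one is a substrate of a reaction catalyzed by the other; (5) score each enzyme
gene as ``auc(module) * (-log10 hypergeometric tail)`` where the tail is the
probability of at least the observed number of within-module metabolic links;
(6) call genes scoring strictly above the median "key" enzymes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import CANCER, ExpressionDataset

__all__ = [
    "CoexpressionNetwork",
    "ModulePartition",
    "Reaction",
    "MetabolicModel",
    "ImportanceScore",
    "build_coexpression_network",
    "partition_modules",
    "module_auc",
    "score_modules",
    "build_enzyme_links",
    "importance_scores",
    "key_enzymes",
    "read_reactions",
    "write_reactions",
    "scores_to_frame",
    "write_scores",
]


@dataclass
class CoexpressionNetwork:
    """Thresholded absolute-correlation gene network (isolated genes retained)."""

    graph: nx.Graph
    min_abs_pcc: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class ModulePartition:
    """Gene -> module assignment, optionally with per-module oriented AUCs."""

    assignment: dict[str, str]
    auc: dict[str, float] = field(default_factory=dict)

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.assignment.items():
            out.setdefault(m, []).append(g)
        return {m: sorted(gs) for m, gs in out.items()}


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    enzyme: str
    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id!r}: needs >=1 substrate and >=1 product"
            )
        if not self.enzyme:
            raise ValueError(f"reaction {self.reaction_id!r}: missing catalyzing enzyme")


@dataclass
class MetabolicModel:
    """Reaction list plus the derived enzyme-enzyme link set.

    ``excluded_compounds`` lists currency metabolites (ATP, H2O, ...) ignored
    when deriving links; empty by default.
    """

    reactions: list[Reaction]
    excluded_compounds: frozenset[str] = frozenset()
    enzyme_links: set[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.excluded_compounds = frozenset(self.excluded_compounds)
        self.enzyme_links = build_enzyme_links(self.reactions, self.excluded_compounds)

    @property
    def enzymes(self) -> list[str]:
        return sorted({r.enzyme for r in self.reactions})

    def compounds(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.substrates | r.products
        return out


@dataclass
class ImportanceScore:
    gene: str
    module: str
    auc: float
    d_in: int
    d_tot: int
    enrichment: float
    score: float
    is_key: bool = False


def build_coexpression_network(
    ds: ExpressionDataset, min_abs_pcc: float = 0.7
) -> CoexpressionNetwork:
    """Join genes whose absolute Pearson correlation reaches ``min_abs_pcc``.

    Zero-variance genes cannot carry edges and are excluded from edge building
    with a warning; every gene remains a node (isolated if unconnected).
    """
    if ds.n_samples < 4:
        raise ValueError("need >=4 samples to estimate correlations")
    X = ds.values
    if np.isnan(X).any():
        raise ValueError("missing values present; run normalize() first")
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) excluded from edges",
            UserWarning,
            stacklevel=2,
        )
    g = nx.Graph()
    g.add_nodes_from(ds.genes)
    ok = np.nonzero(~constant)[0]
    if ok.size >= 2:
        corr = np.corrcoef(X[ok])
        np.fill_diagonal(corr, 0.0)
        ii, jj = np.nonzero(np.triu(np.abs(corr) >= min_abs_pcc, k=1))
        genes = ds.genes
        g.add_weighted_edges_from(
            (genes[ok[i]], genes[ok[j]], float(corr[i, j])) for i, j in zip(ii, jj)
        )
    return CoexpressionNetwork(graph=g, min_abs_pcc=min_abs_pcc)


def partition_modules(net: CoexpressionNetwork, seed: int = 0) -> ModulePartition:
    """Partition the network into modules by seeded modularity maximization.

    Louvain communities (greedy modularity with local-move refinement) on the
    subgraph of connected nodes; isolated genes become singleton modules.
    Module ids are assigned deterministically by decreasing size then by the
    lexicographically smallest member.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    core = sorted(n for n in g if g.degree(n) > 0)
    communities: list[set[str]] = []
    if core:
        communities = [
            set(c)
            for c in nx.community.louvain_communities(g.subgraph(core), weight=None, seed=seed)
        ]
    singles = [{n} for n in sorted(g) if g.degree(n) == 0]
    ordered = sorted(communities, key=lambda c: (-len(c), min(c))) + singles
    width = max(3, len(str(len(ordered))))
    assignment = {
        gene: f"M{k + 1:0{width}d}" for k, comm in enumerate(ordered) for gene in comm
    }
    return ModulePartition(assignment=assignment)


def module_auc(module_genes, ds: ExpressionDataset, _gene_index=None) -> float:
    """Oriented ROC AUC of per-sample module-median expression (cancer vs normal).

    The per-sample score is the median expression of the module genes; AUC is
    the tie-aware pair-counting (Mann-Whitney) statistic, returned as
    ``max(AUC, 1 - AUC)`` so 0.5 is uninformative and 1 is perfectly
    cancer-specific in either direction.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("module has no genes")
    index = _gene_index if _gene_index is not None else ds.gene_index()
    try:
        rows = [index[g] for g in module_genes]
    except KeyError as exc:
        raise ValueError(f"module gene {exc.args[0]!r} absent from dataset") from None
    scores = np.median(ds.values[rows], axis=0)
    y = np.array([lab == CANCER for lab in ds.phenotype])
    nc, nn = int(y.sum()), int((~y).sum())
    if nc == 0 or nn == 0:
        raise ValueError("both phenotype classes must be present")
    r = stats.rankdata(scores)
    auc = (r[y].sum() - nc * (nc + 1) / 2) / (nc * nn)
    return float(max(auc, 1.0 - auc))


def score_modules(partition: ModulePartition, ds: ExpressionDataset) -> ModulePartition:
    """Return a copy of the partition with every module's oriented AUC filled in."""
    index = ds.gene_index()
    auc = {
        m: module_auc(genes, ds, _gene_index=index)
        for m, genes in partition.modules().items()
    }
    return ModulePartition(assignment=dict(partition.assignment), auc=auc)


def build_enzyme_links(
    reactions, excluded_compounds=frozenset()
) -> set[tuple[str, str]]:
    """Link enzymes E1-E2 when a product of an E1 reaction is a substrate of an
    E2 reaction (or vice versa), ignoring excluded (currency) compounds."""
    excluded = frozenset(excluded_compounds)
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for r in reactions:
        for c in r.products - excluded:
            producers.setdefault(c, set()).add(r.enzyme)
        for c in r.substrates - excluded:
            consumers.setdefault(c, set()).add(r.enzyme)
    links: set[tuple[str, str]] = set()
    for c, prod in producers.items():
        for e1 in prod:
            for e2 in consumers.get(c, ()):
                if e1 != e2:
                    links.add((min(e1, e2), max(e1, e2)))
    return links


def importance_scores(
    partition: ModulePartition, model: MetabolicModel
) -> list[ImportanceScore]:
    """Score every enzyme gene: ``auc(module) x (-log10 hypergeometric tail)``.

    For enzyme ``g`` with ``d_tot`` metabolic links among the scored enzymes and
    ``d_in`` of them inside its own module, the tail is the upper hypergeometric
    probability of >= ``d_in`` within-module links when ``d_tot`` links are drawn
    from the scored-enzyme universe of which the module holds its share.
    ``is_key`` marks scores strictly above the median score.
    """
    enzymes = model.enzymes
    scored = [e for e in enzymes if e in partition.assignment]
    skipped = sorted(set(enzymes) - set(scored))
    if skipped:
        warnings.warn(
            f"{len(skipped)} enzyme gene(s) absent from the partition; skipped",
            UserWarning,
            stacklevel=2,
        )
    if not scored:
        raise ValueError("no enzyme gene is present in the partition")
    scored_set = set(scored)
    total = len(scored)
    adj: dict[str, set[str]] = {e: set() for e in scored}
    for a, b in model.enzyme_links:
        if a in scored_set and b in scored_set:
            adj[a].add(b)
            adj[b].add(a)
    module_counts: dict[str, int] = {}
    for e in scored:
        m = partition.assignment[e]
        module_counts[m] = module_counts.get(m, 0) + 1
    needed = set(module_counts)
    missing_auc = sorted(m for m in needed if m not in partition.auc)
    if missing_auc:
        raise ValueError(
            f"module AUCs missing for {missing_auc[:5]}; call score_modules() first"
        )

    results = []
    for e in scored:
        m = partition.assignment[e]
        neigh = adj[e]
        d_tot = len(neigh)
        d_in = sum(1 for h in neigh if partition.assignment[h] == m)
        if d_tot == 0 or d_in == 0:
            tail = 1.0
        else:
            tail = float(stats.hypergeom.sf(d_in - 1, total, module_counts[m], d_tot))
        enrichment = -math.log10(max(tail, 1e-300)) if tail < 1.0 else 0.0
        auc = partition.auc[m]
        results.append(
            ImportanceScore(
                gene=e,
                module=m,
                auc=float(auc),
                d_in=d_in,
                d_tot=d_tot,
                enrichment=float(enrichment),
                score=float(auc * enrichment),
            )
        )
    median = float(np.median([r.score for r in results]))
    for r in results:
        r.is_key = r.score > median
    results.sort(key=lambda r: (-r.score, r.gene))
    return results


def key_enzymes(scores: list[ImportanceScore]) -> set[str]:
    """Genes scoring strictly above the median importance score."""
    if not scores:
        raise ValueError("no importance scores supplied")
    median = float(np.median([s.score for s in scores]))
    return {s.gene for s in scores if s.score > median}


# ---------------------------------------------------------------------------
# TSV interfaces


def read_reactions(path) -> list[Reaction]:
    """Reaction table TSV: reaction_id, enzyme_gene, substrates, products
    (compound lists ``;``-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"reaction_id", "enzyme_gene", "substrates", "products"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    reactions = []
    for row in df.itertuples(index=False):
        reactions.append(
            Reaction(
                reaction_id=row.reaction_id,
                enzyme=row.enzyme_gene,
                substrates=frozenset(c for c in row.substrates.split(";") if c),
                products=frozenset(c for c in row.products.split(";") if c),
            )
        )
    return reactions


def write_reactions(reactions: list[Reaction], path) -> None:
    pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in reactions],
            "enzyme_gene": [r.enzyme for r in reactions],
            "substrates": [";".join(sorted(r.substrates)) for r in reactions],
            "products": [";".join(sorted(r.products)) for r in reactions],
        }
    ).to_csv(path, sep="\t", index=False)


def scores_to_frame(scores: list[ImportanceScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "module": [s.module for s in scores],
            "auc": [s.auc for s in scores],
            "d_in": [s.d_in for s in scores],
            "d_tot": [s.d_tot for s in scores],
            "enrichment": [s.enrichment for s in scores],
            "score": [s.score for s in scores],
            "is_key": [s.is_key for s in scores],
        }
    )


def write_scores(scores: list[ImportanceScore], path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)
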