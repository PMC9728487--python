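"""Gene-set enrichment of Survival scores.

Gene sets come from GMT files or from a GO ontology (OBO) plus a GAF
annotation file, propagating each annotation up the is_a / part_of
closure.  Enrichment is a two-sample Kolmogorov-Smirnov test of the
members' signed scores against the non-members, one-sided toward higher
scores by default, with Benjamini-Hochberg FDR across the tested family
and a delta-score summary (set median minus background median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NAMESPACE_MAP = {
    "biological_process": "process",
    "cellular_component": "compartment",
    "molecular_function": "custom",
}


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    namespace: str  # process | compartment | custom
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    namespace: str
    n: int  # members with a score in the background
    ks_stat: float
    pvalue: float
    delta_survival: float
    fdr: float | None = None


def parse_gaf(path) -> list[tuple[str, str]]:
    """(gene symbol, term id) annotations from a GAF 2.x file.

    Comment lines start with '!'; NOT-qualified annotations are skipped.
    """
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: malformed GAF line")
            qualifier, symbol, term = cols[3], cols[2], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            out.append((symbol, term))
    return out


def build_gene_sets_from_obo_gaf(
    obo_path,
    gaf_path,
    relations: tuple[str, ...] = ("is_a", "part_of"),
) -> list[GeneSet]:
    """Gene sets from an ontology plus annotations.

    Every annotated gene becomes a member of its term's set and of every
    ancestor reachable through the chosen relations.  Obsolete terms are
    not loaded; annotations to unknown terms are skipped with a warning.
    """
    import obonet

    graph = obonet.read_obo(obo_path)
    sub = nx.MultiDiGraph()
    sub.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in relations:
            sub.add_edge(child, parent, key=key)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise ValueError(f"ontology cycle over {relations}: {cycle}")

    annotations = parse_gaf(gaf_path)
    if not annotations:
        logger.warning("empty annotation file %s", gaf_path)
    members: dict[str, set[str]] = {}
    unknown = 0
    for gene, term in annotations:
        if term not in sub:
            unknown += 1
            continue
        for t in (term, *nx.descendants(sub, term)):  # edges point child->parent
            members.setdefault(t, set()).add(gene)
    if unknown:
        logger.warning("skipped %d annotations to unknown terms", unknown)

    sets = []
    for term, genes in sorted(members.items()):
        data = sub.nodes[term]
        sets.append(
            GeneSet(
                set_id=term,
                name=data.get("name", term),
                namespace=NAMESPACE_MAP.get(data.get("namespace", ""), "custom"),
                members=frozenset(genes),
            )
        )
    return sets


def filter_min_perturbations(scores: pd.DataFrame, k: int = 3) -> pd.Series:
    """Enrichment background: Survival scores of proteins measured in at
    least ``k`` perturbations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    required = {"survival_score", "n_perturbations"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table missing columns: {sorted(required)}")
    kept = scores.loc[scores["n_perturbations"] >= k, "survival_score"].dropna()
    if kept.empty:
        raise ValueError(
            f"no protein measured in >= {k} perturbations; lower k"
        )
    return kept


def ks_signed_enrichment(
    gene_set: GeneSet,
    background: pd.Series,
    side: str = "greater",
    min_size: int = 5,
) -> EnrichmentResult | None:
    """Two-sample KS enrichment of a set's signed scores vs non-members.

    ``side='greater'`` tests a shift of the members toward higher scores;
    'two-sided' tests any distributional difference.  Sets with fewer than
    ``min_size`` scored members return None (logged).  delta_survival is
    the member median minus the median of the whole background.
    """
    if side not in ("greater", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    in_set = background.index.isin(gene_set.members)
    member_scores = background[in_set]
    other_scores = background[~in_set]
    if len(member_scores) < min_size or other_scores.empty:
        logger.info(
            "set %s below min_size (%d scored members)",
            gene_set.set_id,
            len(member_scores),
        )
        return None
    alternative = "less" if side == "greater" else "two-sided"
    res = stats.ks_2samp(
        member_scores.to_numpy(),
        other_scores.to_numpy(),
        alternative=alternative,
        method="auto",
    )
    delta = float(member_scores.median() - background.median())
    return EnrichmentResult(
        set_id=gene_set.set_id,
        name=gene_set.name,
        namespace=gene_set.namespace,
        n=int(len(member_scores)),
        ks_stat=float(res.statistic),
        pvalue=float(res.pvalue),
        delta_survival=delta,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_sets(
    gene_sets: list[GeneSet],
    background: pd.Series,
    side: str = "greater",
    min_size: int = 5,
    fdr_by_namespace: bool = True,
) -> pd.DataFrame:
    """Test every set, BH-correct (per namespace family by default), and
    return a tidy table sorted by set id."""
    results = []
    for gs in gene_sets:
        r = ks_signed_enrichment(gs, background, side=side, min_size=min_size)
        if r is not None:
            results.append(r)
    if not results:
        return pd.DataFrame(
            columns=[
                "set_id",
                "name",
                "namespace",
                "n",
                "ks_stat",
                "pvalue",
                "fdr",
                "delta_survival_score",
            ]
        )
    df = pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "namespace": [r.namespace for r in results],
            "n": [r.n for r in results],
            "ks_stat": [r.ks_stat for r in results],
            "pvalue": [r.pvalue for r in results],
            "delta_survival_score": [r.delta_survival for r in results],
        }
    )
    df["fdr"] = np.nan
    groups = df.groupby("namespace").groups if fdr_by_namespace else {"all": df.index}
    for _, idx in groups.items():
        df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "pvalue"].to_numpy())
    df = df[
        [
            "set_id",
            "name",
            "namespace",
            "n",
            "ks_stat",
            "pvalue",
            "fdr",
            "delta_survival_score",
        ]
    ]
    return df.sort_values("set_id").reset_index(drop=True)
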