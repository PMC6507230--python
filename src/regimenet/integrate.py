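"""Query-based multi-omics subgroup networks.

A subgroup query is a conjunction of (gene, regime/aberration)
conditions — e.g. "MLPH low and FOXA1 low" — defining a set of samples.
All expression regimes, mutations, deletions and amplifications that
co-occur significantly with that sample set are collected (expression
at log10 p <= -50 by default, genomic events at <= -20), copy-number
events are checked for cis consistency with the same gene's expression
regimes, and the passing genes are mapped onto a reference interaction
network. Retained edges must satisfy the conditional-probability link
filter (P(A_i|B_j) > 0.5 or P(B_j|A_i) > 0.5) and are oriented by the
heuristic that the better-predicted event is downstream: if
P(A_i|B_j) > P(B_j|A_i) then B_j -> A_i, which makes the rarer event
the source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .associations import (
    AssociationError,
    EventSet,
    cooccurrence_log10_p,
)
from .discretize import MISSING_CODE, RegimeMatrix
from .io import AMP, DEL, AberrationMatrix, InteractionNetwork

MIN_MUTATED_SAMPLES = 3  # mutation events with fewer carriers are not scored

DEFAULT_EXPR_LOG10P = -50.0
DEFAULT_GENOMIC_LOG10P = -20.0


class IntegrationError(ValueError):
    pass


@dataclass
class SubgroupQuery:
    """Conjunction of conditions plus the modality significance thresholds."""

    conditions: list[tuple[str, str, str]]  # (feature_id, modality, category)
    expr_log10_p_max: float = DEFAULT_EXPR_LOG10P
    genomic_log10_p_max: float = DEFAULT_GENOMIC_LOG10P
    cis_log10_p_max: float = DEFAULT_GENOMIC_LOG10P

    def __post_init__(self) -> None:
        if not self.conditions:
            raise IntegrationError("a subgroup query needs at least one condition")
        for t in (self.expr_log10_p_max, self.genomic_log10_p_max, self.cis_log10_p_max):
            if t > 0:
                raise IntegrationError("log10 p thresholds must be <= 0")

    @property
    def query_genes(self) -> set[str]:
        return {c[0] for c in self.conditions}

    @classmethod
    def parse(cls, text: str, **thresholds) -> "SubgroupQuery":
        """Parse "GENE:low,GENE2:high,GENE3:MUT" style query strings."""
        conds = []
        for part in text.split(","):
            feat, _, cat = part.strip().partition(":")
            if not feat or not cat:
                raise IntegrationError(f"malformed query condition {part!r}")
            cat = cat.strip()
            if cat in ("MUT",):
                conds.append((feat, "mutation", "MUT"))
            elif cat in ("DEL", "AMP"):
                conds.append((feat, "cnv", cat))
            else:
                regime = {"low": "0", "high": "1"}.get(cat, cat)
                conds.append((feat, "expression", regime))
        return cls(conds, **thresholds)


@dataclass
class SubgroupNetwork:
    """Significantly co-occurring genes with attributes and directed edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    n_mapped: int = 0
    n_unmapped: int = 0


# ---------------------------------------------------------------------------
# event construction


def regime_event(
    rm: RegimeMatrix, gene: str, regime: int, samples: Optional[list[str]] = None
) -> EventSet:
    if gene not in rm.profiles:
        raise IntegrationError(f"gene {gene!r} absent from regime matrix")
    if not (0 <= regime < rm.k_of(gene)):
        raise IntegrationError(f"gene {gene!r} has no regime {regime}")
    samples = samples if samples is not None else rm.sample_ids
    row = rm.codes.loc[gene]
    support = frozenset(s for s in samples if row[s] == regime)
    universe = frozenset(s for s in samples if row[s] != MISSING_CODE)
    return EventSet(gene, str(regime), support, len(universe), universe)


def aberration_event(
    ab: AberrationMatrix, gene: str, category: str,
    samples: Optional[list[str]] = None,
) -> EventSet:
    if gene not in ab.values.index:
        raise IntegrationError(f"gene {gene!r} absent from {ab.kind} matrix")
    samples = samples if samples is not None else ab.sample_ids
    row = ab.values.loc[gene]
    if category == "MUT":
        if ab.kind != "mutation":
            raise IntegrationError("MUT event requires a mutation matrix")
        support = frozenset(s for s in samples if row[s] == 1)
    elif category in ("DEL", "AMP"):
        if ab.kind != "cnv":
            raise IntegrationError(f"{category} event requires a cnv matrix")
        target = DEL if category == "DEL" else AMP
        # accept either 5-level or collapsed 3-class input
        support = frozenset(s for s in samples if np.sign(row[s]) == target)
    else:
        raise IntegrationError(f"unknown aberration category {category!r}")
    return EventSet(gene, category, support, len(samples), frozenset(samples))


def subgroup_indicator(
    query: SubgroupQuery,
    rm: RegimeMatrix,
    mut: Optional[AberrationMatrix] = None,
    cnv: Optional[AberrationMatrix] = None,
) -> EventSet:
    """Intersect the query conditions' supports over the aligned universe."""
    universes = []
    supports = []
    for feat, modality, category in query.conditions:
        if modality == "expression":
            ev = regime_event(rm, feat, int(category))
            universes.append(set(rm.sample_ids))
        elif modality == "mutation":
            if mut is None:
                raise IntegrationError("query uses mutations but none provided")
            ev = aberration_event(mut, feat, category)
            universes.append(set(mut.sample_ids))
        elif modality == "cnv":
            if cnv is None:
                raise IntegrationError("query uses cnv but none provided")
            ev = aberration_event(cnv, feat, category)
            universes.append(set(cnv.sample_ids))
        else:
            raise IntegrationError(f"unknown modality {modality!r}")
        supports.append(set(ev.support))
    universe = set.intersection(*universes)
    support = set.intersection(*supports) & universe
    label = "&".join(f"{f}:{c}" for f, _, c in query.conditions)
    return EventSet(
        label, "SUBGROUP", frozenset(support), len(universe), frozenset(universe)
    )


# ---------------------------------------------------------------------------
# subgroup association scan


def _score_against(
    sub: EventSet, ev: EventSet, universe: set
) -> tuple[float, int, int, int, int]:
    """Co-occurrence of a candidate event with the subgroup on the shared
    universe (samples observed for both modalities)."""
    n = len(universe)
    if n == 0:
        return 0.0, 0, 0, 0, 0
    a = set(sub.support) & universe
    b = set(ev.support) & universe
    n_ab = len(a & b)
    lp = cooccurrence_log10_p(len(a), len(b), n_ab, n)
    return lp, len(a), len(b), n_ab, n


def subgroup_associations(
    sub: EventSet,
    rm: RegimeMatrix,
    mut: Optional[AberrationMatrix] = None,
    cnv: Optional[AberrationMatrix] = None,
    query: Optional[SubgroupQuery] = None,
) -> dict[str, pd.DataFrame]:
    """All events significantly co-occurring with the subgroup, per modality.

    Expression regimes are kept at log10 p <= expr threshold (best
    regime per gene reported); mutations and DEL/AMP copy-number states
    at the genomic threshold. CNV events additionally record whether
    they are cis-consistent with the same gene's expression regimes.
    """
    if sub.n == 0:
        raise IntegrationError("empty subgroup support")
    thresholds = query or SubgroupQuery([("_", "expression", "0")])
    query_genes = query.query_genes if query else set()
    rm_samples = set(rm.sample_ids)
    sub_universe = set(sub.universe) if sub.universe is not None else rm_samples

    out: dict[str, pd.DataFrame] = {}

    rows = []
    for gene in rm.multimodal_genes():
        best = None
        for regime in range(rm.k_of(gene)):
            ev = regime_event(rm, gene, regime)
            # universe = samples observed for the subgroup's modalities
            # and for this candidate gene
            universe = sub_universe & set(ev.universe)
            lp, na, nb, nab, n = _score_against(sub, ev, universe)
            if best is None or lp < best[0]:
                best = (lp, regime, na, nb, nab, n)
        lp, regime, na, nb, nab, n = best
        if lp <= thresholds.expr_log10_p_max:
            rows.append(
                {"gene": gene, "regime": regime, "n": n, "n_sub": na,
                 "n_event": nb, "n_both": nab, "log10_p": lp,
                 "p_event_given_sub": nab / na if na else float("nan"),
                 "p_sub_given_event": nab / nb if nb else float("nan"),
                 "is_query_gene": gene in query_genes}
            )
    out["expression"] = _finish(rows, _EXPR_COLS)

    if mut is not None:
        rows = []
        universe = sub_universe & set(mut.sample_ids)
        for gene in mut.gene_ids:
            ev = aberration_event(mut, gene, "MUT")
            if len(set(ev.support) & universe) < MIN_MUTATED_SAMPLES:
                continue
            lp, na, nb, nab, n = _score_against(sub, ev, universe)
            if lp <= thresholds.genomic_log10_p_max:
                rows.append(
                    {"gene": gene, "category": "MUT", "n": n, "n_sub": na,
                     "n_event": nb, "n_both": nab, "log10_p": lp,
                     "is_query_gene": gene in query_genes}
                )
        out["mutation"] = _finish(rows, _MUT_COLS)

    if cnv is not None:
        rows = []
        universe = sub_universe & set(cnv.sample_ids)
        for gene in cnv.gene_ids:
            for category in ("DEL", "AMP"):  # NEUT is never tested as an event
                ev = aberration_event(cnv, gene, category)
                if not ev.support:
                    continue
                lp, na, nb, nab, n = _score_against(sub, ev, universe)
                if lp <= thresholds.genomic_log10_p_max:
                    rows.append(
                        {"gene": gene, "category": category, "n": n,
                         "n_sub": na, "n_event": nb, "n_both": nab,
                         "log10_p": lp,
                         "cis_consistent": cis_consistency(
                             ev, rm, thresholds.cis_log10_p_max
                         ),
                         "is_query_gene": gene in query_genes}
                    )
        out["cnv"] = _finish(rows, _CNV_COLS)

    return out


_EXPR_COLS = ["gene", "regime", "n", "n_sub", "n_event", "n_both", "log10_p",
              "p_event_given_sub", "p_sub_given_event", "is_query_gene"]
_MUT_COLS = ["gene", "category", "n", "n_sub", "n_event", "n_both", "log10_p",
             "is_query_gene"]
_CNV_COLS = ["gene", "category", "n", "n_sub", "n_event", "n_both", "log10_p",
             "cis_consistent", "is_query_gene"]


def _finish(rows: list[dict], columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    if not df.empty:
        df = df.sort_values(["log10_p", "gene"], kind="stable").reset_index(drop=True)
    return df


def cis_consistency(
    cnv_event: EventSet, rm: RegimeMatrix, threshold: float = DEFAULT_GENOMIC_LOG10P
) -> bool:
    """Does this copy-number event co-occur with an expression regime of
    the same gene below the threshold? Unimodal or absent genes: False."""
    gene = cnv_event.feature_id
    prof = rm.profiles.get(gene)
    if prof is None:
        warnings.warn(f"cis check: gene {gene!r} absent from expression")
        return False
    if prof.k < 2:
        return False
    cnv_universe = (
        set(cnv_event.universe) if cnv_event.universe is not None
        else set(rm.sample_ids)
    )
    for regime in range(prof.k):
        ev = regime_event(rm, gene, regime)
        lp, *_ = _score_against(cnv_event, ev, cnv_universe & set(ev.universe))
        if lp <= threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# direction and network assembly


def direction(event_a: EventSet, event_b: EventSet, n_ab: int) -> str:
    """Orient an association edge from its conditional probabilities.

    P(A|B) > P(B|A) means B predicts A better than the reverse, read as
    B -> A; equality (equal supports) leaves the edge undirected. With a
    shared co-occurrence count this reduces to: the rarer event is the
    source.
    """
    if event_a.n == 0 or event_b.n == 0:
        warnings.warn("zero-support conditioning; edge left undirected")
        return "undirected"
    p_a_given_b = n_ab / event_b.n
    p_b_given_a = n_ab / event_a.n
    if p_a_given_b > p_b_given_a:
        return "b->a"
    if p_b_given_a > p_a_given_b:
        return "a->b"
    return "undirected"


def build_subgroup_network(
    assoc: dict[str, pd.DataFrame],
    rm: RegimeMatrix,
    net: InteractionNetwork,
    link_filter: float = 0.5,
) -> SubgroupNetwork:
    """Map passing genes onto the reference network and orient the edges.

    Nodes carry regime (low/high for binary genes), mutated / amplified
    / deleted flags and the query-gene flag. Edges exist only where the
    reference network has the interaction, both genes carry an
    expression regime event, and the link filter holds: max of the two
    conditionals > ``link_filter``.
    """
    expr = assoc.get("expression", pd.DataFrame())
    g = nx.DiGraph()
    regime_of: dict[str, int] = {}
    for _, row in expr.iterrows():
        gene = row["gene"]
        regime = int(row["regime"])
        regime_of[gene] = regime
        regime_name = {0: "low", 1: "high"}.get(regime, str(regime))
        g.add_node(
            gene, regime=regime_name, mutated=False, amplified=False,
            deleted=False, is_query_gene=bool(row["is_query_gene"]),
        )
    for modality, flag_of in (("mutation", {"MUT": "mutated"}),
                              ("cnv", {"DEL": "deleted", "AMP": "amplified"})):
        for _, row in assoc.get(modality, pd.DataFrame()).iterrows():
            gene = row["gene"]
            if gene not in g:
                g.add_node(
                    gene, regime="none", mutated=False, amplified=False,
                    deleted=False, is_query_gene=bool(row["is_query_gene"]),
                )
            g.nodes[gene][flag_of[row["category"]]] = True

    mapped = [n for n in g.nodes if n in net.graph]
    unmapped = [n for n in g.nodes if n not in net.graph]

    for a, b in net.graph.edges():
        if a in regime_of and b in regime_of and a in g and b in g:
            ev_a = regime_event(rm, a, regime_of[a])
            ev_b = regime_event(rm, b, regime_of[b])
            n_ab = len(set(ev_a.support) & set(ev_b.support))
            try:
                p_ab = n_ab / ev_b.n
                p_ba = n_ab / ev_a.n
            except ZeroDivisionError:
                continue
            if max(p_ab, p_ba) <= link_filter:
                continue
            dirn = direction(ev_a, ev_b, n_ab)
            attrs = {
                "p_a_given_b": p_ab, "p_b_given_a": p_ba,
                "in_reference_network": True,
            }
            if dirn == "b->a":
                g.add_edge(b, a, direction="directed", **attrs)
            elif dirn == "a->b":
                g.add_edge(a, b, direction="directed", **attrs)
            else:
                g.add_edge(a, b, direction="undirected", **attrs)
    return SubgroupNetwork(graph=g, n_mapped=len(mapped), n_unmapped=len(unmapped))


def query_distances(net: InteractionNetwork, query_gene: str) -> dict[str, int]:
    """Shortest-path distance from a query gene on the reference network."""
    if query_gene not in net.graph:
        return {}
    return dict(nx.single_source_shortest_path_length(net.graph, query_gene))


# ---------------------------------------------------------------------------
# export


def export_network(snet: SubgroupNetwork, prefix: str) -> list[str]:
    """Write SIF, GraphML and node-attribute TSV for Cytoscape-style use."""
    paths = []
    sif = f"{prefix}.sif"
    with open(sif, "w", encoding="utf-8") as fh:
        for a, b in sorted(snet.graph.edges()):
            fh.write(f"{a}\tcooc\t{b}\n")
    paths.append(sif)

    gml = f"{prefix}.graphml"
    nx.write_graphml(snet.graph, gml)
    paths.append(gml)

    nodes = f"{prefix}.nodes.tsv"
    rows = [
        {"gene": n, **{k: v for k, v in snet.graph.nodes[n].items()}}
        for n in sorted(snet.graph.nodes)
    ]
    cols = ["gene", "regime", "mutated", "amplified", "deleted", "is_query_gene"]
    pd.DataFrame(rows, columns=cols).to_csv(nodes, sep="\t", index=False)
    paths.append(nodes)
    return paths
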