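"""Target-gene-based cooperativity indices.

These indices look at what a predicted cooperative TF pair regulates
rather than at the TFs themselves.

1. **Co-regulation** — lookup of the pair in a co-regulatory coefficient
   table (a network of significant shared-target associations, consumed as
   data); pairs absent from the table score 0, since absence from the
   co-regulatory network means no significant association.
2-4. **Coherence scores** (ECS / FCS / PCS) — take the m common target
   genes of the pair, form all C(m, 2) unordered gene pairs A, and report
   the fraction of scored pairs in A whose pairwise score is strictly
   above a global 95th-percentile threshold of the backing table
   (co-expression for ECS, functional similarity for FCS, PPI-overlap
   significance for PCS).  Coherence lies in [0, 1] and is undefined when
   m < 2 or no pair in A is scored.

PCS shares the hypergeometric partner-overlap computation with the
TF-based module; :func:`build_ppi_similarity_table` batches it over a gene
set so the same table serves both the coherence lookup and the
percentile-threshold derivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np

from .resources import (
    PairScoreTable,
    PCTFPSet,
    PPINetwork,
    RegulonMap,
    ScoreThreshold,
    TFPair,
    common_targets,
)
from .tf_indices import (
    DEFAULT_UNIVERSE_SIZE,
    IndexResult,
    PairScore,
    _summarize_pairs,
    hypergeom_overlap_scores,
    ppi_partner_overlap_score,
)

logger = logging.getLogger("tfcoop")

TG_INDEX_LABELS = (
    "tg1_coregulation",
    "tg2_expression_coherence",
    "tg3_functional_coherence",
    "tg4_ppi_coherence",
)


@dataclass
class CoherenceResult:
    """Coherence of one pair's common-target gene pairs against a threshold."""

    pair: TFPair
    n_common_targets: int
    n_gene_pairs: int
    n_scored: int
    n_above: int
    score: float | None
    reason: str | None = None

    def as_pair_score(self) -> PairScore:
        return PairScore(
            pair=self.pair,
            value=self.score,
            reason=self.reason,
            detail={
                "n_common_targets": self.n_common_targets,
                "n_gene_pairs": self.n_gene_pairs,
                "n_scored": self.n_scored,
                "n_above": self.n_above,
            },
        )


def coregulation_score(coef_table: PairScoreTable, pair: TFPair) -> PairScore:
    """Co-regulatory coefficient lookup; absent pairs score 0 (index TG-1)."""
    value = coef_table.get(pair.a, pair.b)
    if value is None:
        return PairScore(pair=pair, value=0.0, detail={"in_table": False})
    return PairScore(pair=pair, value=value, detail={"in_table": True})


def ppi_similarity(
    net: PPINetwork, gene_pair: TFPair, universe_size: int = DEFAULT_UNIVERSE_SIZE
) -> float:
    """Partner-overlap significance of an arbitrary gene pair.

    Identical to the TF-based partner-overlap index; kept as one shared
    implementation so PCS lookups equal per-pair index-1 scores exactly.
    """
    return ppi_partner_overlap_score(net, gene_pair, universe_size).value


def build_ppi_similarity_table(
    net: PPINetwork,
    genes: Iterable[str],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> PairScoreTable:
    """Batch partner-overlap significance over all unordered pairs of ``genes``.

    Vectorized via the adjacency structure: common-partner counts for all
    pairs come from one sparse matrix product, then a single vectorized
    hypergeometric tail call.
    """
    import networkx as nx
    from scipy import sparse

    gene_list = sorted({g.strip() for g in genes})
    table = PairScoreTable(description="ppi_similarity")
    if len(gene_list) < 2:
        return table

    in_graph = [g for g in gene_list if g in net.graph]
    degrees = {g: net.degree(g) for g in gene_list}

    # common-partner counts via B @ B.T, B = rows of the adjacency matrix
    c_lookup: dict[tuple[int, int], int] = {}
    if len(in_graph) >= 2:
        nodes = list(net.graph.nodes)
        adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, format="csr")
        node_idx = {n: i for i, n in enumerate(nodes)}
        rows = adj[[node_idx[g] for g in in_graph], :]
        common = (rows @ rows.T).tocoo()
        pos = {g: i for i, g in enumerate(in_graph)}
        for i, j, v in zip(common.row, common.col, common.data):
            if i < j:
                c_lookup[(i, j)] = int(v)
        in_graph_pos = pos
    else:
        in_graph_pos = {}

    pairs = list(combinations(gene_list, 2))
    c = np.zeros(len(pairs), dtype=np.int64)
    n1 = np.array([degrees[a] for a, _ in pairs], dtype=np.int64)
    n2 = np.array([degrees[b] for _, b in pairs], dtype=np.int64)
    for k, (a, b) in enumerate(pairs):
        ia, ib = in_graph_pos.get(a), in_graph_pos.get(b)
        if ia is not None and ib is not None:
            key = (ia, ib) if ia < ib else (ib, ia)
            c[k] = c_lookup.get(key, 0)
    scores = hypergeom_overlap_scores(c, universe_size, n1, n2)
    for (a, b), s in zip(pairs, scores):
        table.set(a, b, float(s))
    return table


def coherence_score(
    pair: TFPair,
    regulons: RegulonMap,
    scores: PairScoreTable,
    threshold: ScoreThreshold,
    missing_policy: str = "exclude",
) -> CoherenceResult:
    """Fraction of common-target gene pairs scoring strictly above the threshold.

    ``missing_policy`` controls gene pairs absent from the score table:
    ``exclude`` (default) drops them from numerator and denominator,
    ``zero`` treats them as scores of 0 (counted, never above a
    nonnegative threshold).
    """
    if missing_policy not in ("exclude", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    targets = sorted(common_targets(regulons, pair))
    m = len(targets)
    gene_pairs = list(combinations(targets, 2))
    if m < 2:
        return CoherenceResult(pair, m, 0, 0, 0, None, reason="fewer_than_2_common_targets")
    n_scored = n_above = n_missing = 0
    for a, b in gene_pairs:
        s = scores.get(a, b)
        if s is None:
            n_missing += 1
            if missing_policy == "zero":
                n_scored += 1
                n_above += 0.0 > threshold.value
            continue
        n_scored += 1
        if s > threshold.value:
            n_above += 1
    if n_missing:
        logger.debug("coherence %s-%s: %d unscored gene pair(s) (%s)",
                     pair.a, pair.b, n_missing, missing_policy)
    if n_scored == 0:
        return CoherenceResult(pair, m, len(gene_pairs), 0, 0, None, reason="no_scored_pairs")
    return CoherenceResult(pair, m, len(gene_pairs), n_scored, int(n_above), n_above / n_scored)


def evaluate_tg_indices(
    pctfp_set: PCTFPSet,
    regulons: RegulonMap,
    coregulation: PairScoreTable,
    coexpression: PairScoreTable,
    functional: PairScoreTable,
    ppi_sim: PairScoreTable,
    thresholds: dict[str, ScoreThreshold],
    stat: str = "mean",
    missing_policy: str = "exclude",
) -> dict[str, IndexResult]:
    """All four TG-based indices for one predicted set.

    ``thresholds`` maps the three coherence labels to 95th-percentile
    thresholds derived from the full backing tables (co-expression,
    functional similarity, PPI similarity).
    """
    results = {
        TG_INDEX_LABELS[0]: _summarize_pairs(
            TG_INDEX_LABELS[0],
            [coregulation_score(coregulation, p) for p in pctfp_set.pairs],
            stat,
        )
    }
    for label, table in (
        (TG_INDEX_LABELS[1], coexpression),
        (TG_INDEX_LABELS[2], functional),
        (TG_INDEX_LABELS[3], ppi_sim),
    ):
        per_pair = [
            coherence_score(p, regulons, table, thresholds[label], missing_policy).as_pair_score()
            for p in pctfp_set.pairs
        ]
        results[label] = _summarize_pairs(label, per_pair, stat)
    return results
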