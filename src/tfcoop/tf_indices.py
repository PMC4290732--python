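"""TF-based cooperativity indices.

Four indices score a predicted cooperative TF pair (PCTFP) — or, for the
benchmark-overlap index, a whole predicted set — from the point of view of
the TFs themselves:

1. **PPI partner overlap** — the upper hypergeometric tail probability of
   the observed number of shared physical-interaction partners,

   .. math::

      P = \\sum_{i=c}^{\\min(N_1, N_2)}
          \\frac{\\binom{N_1}{i} \\binom{N - N_1}{N_2 - i}}{\\binom{N}{N_2}},
      \\qquad S = -\\log_{10} P,

   where ``c`` is the common-partner count, ``N1``/``N2`` the partner
   counts of the two TFs and ``N`` the gene-universe size (6575 unique
   genes for S. cerevisiae).
2. **Shortest path** — ``S = 1/L`` for the unweighted shortest-path length
   ``L`` between the TFs in the physical PPI network (0 when unreachable).
3. **Functional similarity** — lookup in a precomputed semantic-similarity
   table (Jiang–Conrath over GO, consumed as data).
4. **Benchmark overlap** — one-sided Fisher exact enrichment of a predicted
   set against a benchmark of known cooperative pairs, reported as
   ``-log10(P)``.

Per-pair indices are summarized over a set by mean (default) or median of
the defined per-pair scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import mean, median

import numpy as np
from scipy import stats

from .resources import BenchmarkPairSet, PairScoreTable, PCTFPSet, PPINetwork, TFPair

logger = logging.getLogger("tfcoop")

#: Default hypergeometric universe size: unique genes in the yeast genome database.
DEFAULT_UNIVERSE_SIZE = 6575

#: P-values are floored here before taking logs, to keep scores finite.
P_FLOOR = 1e-300

TF_INDEX_LABELS = (
    "tf1_ppi_overlap",
    "tf2_shortest_path",
    "tf3_functional_similarity",
    "tf4_benchmark_overlap",
)


@dataclass
class PairScore:
    """Score of a single pair under one index; ``value`` is None when undefined."""

    pair: TFPair
    value: float | None
    reason: str | None = None  # set when value is None
    detail: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None


def neg_log10(p: float) -> float:
    return -math.log10(max(p, P_FLOOR))


def hypergeom_overlap_pvalue(c: int, universe_size: int, n1: int, n2: int) -> float:
    """Upper-tail P(X >= c) for the overlap of two fixed-size subsets of the universe."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if universe_size < max(n1, n2):
        raise ValueError(
            f"universe_size={universe_size} smaller than a partner count ({n1}, {n2})"
        )
    if c <= 0:
        return 1.0
    # population universe_size, n1 marked, n2 drawn
    return float(stats.hypergeom.sf(c - 1, universe_size, n1, n2))


def hypergeom_overlap_scores(
    c: np.ndarray, universe_size: int, n1: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Vectorized ``-log10`` upper-tail overlap significance (used for batch tables)."""
    c = np.asarray(c, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    if int(max(n1.max(initial=0), n2.max(initial=0))) > universe_size:
        raise ValueError("universe_size smaller than a partner count")
    p = np.ones(c.shape, dtype=float)
    pos = c > 0
    if pos.any():
        p[pos] = stats.hypergeom.sf(c[pos] - 1, universe_size, n1[pos], n2[pos])
    return -np.log10(np.maximum(p, P_FLOOR))


def ppi_partner_overlap_score(
    net: PPINetwork, pair: TFPair, universe_size: int = DEFAULT_UNIVERSE_SIZE
) -> PairScore:
    """Significance of the two TFs' shared PPI partners (index 1).

    A TF absent from the network has an empty partner set, giving c = 0,
    P = 1 and S = 0.  The score is symmetric in pair order.
    """
    pa = net.partners(pair.a)
    pb = net.partners(pair.b)
    c, n1, n2 = len(pa & pb), len(pa), len(pb)
    p = hypergeom_overlap_pvalue(c, universe_size, n1, n2)
    return PairScore(
        pair=pair,
        value=neg_log10(p),
        detail={"c": c, "N1": n1, "N2": n2, "P": p, "N": universe_size},
    )


def shortest_path_score(net: PPINetwork, pair: TFPair) -> PairScore:
    """Inverse shortest-path length between the TFs in the PPI network (index 2).

    Score 0 when the TFs are unreachable from each other or absent from
    the network (the limit of 1/L as L grows without bound).
    """
    length = net.shortest_path_length(pair.a, pair.b)
    if length is None:
        return PairScore(pair=pair, value=0.0, detail={"path_length": None})
    return PairScore(pair=pair, value=1.0 / length, detail={"path_length": length})


def functional_similarity_score(table: PairScoreTable, pair: TFPair) -> PairScore:
    """Precomputed semantic-similarity lookup (index 3); undefined when absent."""
    value = table.get(pair.a, pair.b)
    if value is None:
        return PairScore(pair=pair, value=None, reason="missing")
    return PairScore(pair=pair, value=value)


def benchmark_overlap_score(
    pctfp_set: PCTFPSet,
    benchmark: BenchmarkPairSet,
    universe_pair_count: int | None = None,
    drop_outside_universe: bool = True,
) -> float:
    """One-sided Fisher enrichment of a predicted set in the benchmark (index 4).

    The 2x2 table is built over the universe of possible TF pairs
    (default: all unordered pairs of the benchmark's TF universe).
    Predicted pairs whose TFs fall outside that universe are dropped with
    a logged count (or kept, inflating the margin, when
    ``drop_outside_universe`` is False).  Returns ``-log10`` of the
    enrichment P-value.
    """
    bench = set(benchmark.pairs)
    predicted = pctfp_set.pair_set()
    if universe_pair_count is None:
        n_tf = len(benchmark.tf_universe)
        universe_pair_count = n_tf * (n_tf - 1) // 2
    if universe_pair_count <= 0:
        raise ValueError("universe_pair_count must be positive")

    universe_tfs = set(benchmark.tf_universe)
    outside = {p for p in predicted if not (p.a in universe_tfs and p.b in universe_tfs)}
    if outside and drop_outside_universe:
        logger.info(
            "benchmark_overlap_score[%s]: dropped %d pair(s) outside the TF universe",
            pctfp_set.name, len(outside),
        )
        predicted = predicted - outside

    k = len(predicted & bench)
    n_pred, n_bench = len(predicted), len(bench)
    if universe_pair_count < len(predicted | bench) or universe_pair_count < max(n_pred, n_bench):
        raise ValueError(
            f"universe_pair_count={universe_pair_count} smaller than the table margins"
        )
    table = [
        [k, n_pred - k],
        [n_bench - k, universe_pair_count - n_pred - n_bench + k],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return neg_log10(float(p))


def summarize(values: list[float], stat: str) -> float:
    if stat == "mean":
        return float(mean(values))
    if stat == "median":
        return float(median(values))
    raise ValueError(f"unknown summary statistic {stat!r}")


@dataclass
class IndexResult:
    """Set-level result of one index: summary score plus per-pair diagnostics."""

    label: str
    score: float | None
    per_pair: list[PairScore] = field(default_factory=list)
    n_undefined: int = 0


def _summarize_pairs(label: str, per_pair: list[PairScore], stat: str) -> IndexResult:
    defined = [ps.value for ps in per_pair if ps.defined]
    n_undef = len(per_pair) - len(defined)
    if n_undef:
        logger.info("%s: excluded %d undefined pair score(s)", label, n_undef)
    score = summarize(defined, stat) if defined else None
    return IndexResult(label=label, score=score, per_pair=per_pair, n_undefined=n_undef)


def evaluate_tf_indices(
    pctfp_set: PCTFPSet,
    net: PPINetwork,
    similarity: PairScoreTable,
    benchmark: BenchmarkPairSet,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    universe_pair_count: int | None = None,
    stat: str = "mean",
) -> dict[str, IndexResult]:
    """All four TF-based indices for one predicted set.

    Indices 1–3 summarize per-pair scores over defined pairs only; index 4
    is computed at the set level and carries no per-pair list.
    """
    results = {
        TF_INDEX_LABELS[0]: _summarize_pairs(
            TF_INDEX_LABELS[0],
            [ppi_partner_overlap_score(net, p, universe_size) for p in pctfp_set.pairs],
            stat,
        ),
        TF_INDEX_LABELS[1]: _summarize_pairs(
            TF_INDEX_LABELS[1],
            [shortest_path_score(net, p) for p in pctfp_set.pairs],
            stat,
        ),
        TF_INDEX_LABELS[2]: _summarize_pairs(
            TF_INDEX_LABELS[2],
            [functional_similarity_score(similarity, p) for p in pctfp_set.pairs],
            stat,
        ),
    }
    results[TF_INDEX_LABELS[3]] = IndexResult(
        label=TF_INDEX_LABELS[3],
        score=benchmark_overlap_score(pctfp_set, benchmark, universe_pair_count),
    )
    return results
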