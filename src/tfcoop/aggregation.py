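"""Comprehensive ranking of predicted-set index scores, plus robustness checks.

A study-by-index score matrix (rows: predicted sets, columns: the eight
indices) is summarized by two schemes:

* **Sum of ranking scores** — within each index, studies are ranked by
  score descending (rank 1 = best) with competition (minimum) ranking for
  ties; the comprehensive ranking score of a study is the sum of its eight
  per-index ranks, and the final ranking orders these totals ascending.
* **Sum of normalized scores** — each study's score on index j is divided
  by the column maximum, ``NS_j(i) = OS_j(i) / max_k OS_j(k)``, so the
  per-index best study scores exactly 1; the summarized score
  ``SS(i) = sum_j NS_j(i)`` is ranked descending.

The robustness checks correlate two final ranking lists (mean vs median
summaries, or the two schemes against each other) with a Pearson
product-moment correlation whose P-value comes from the t statistic
``r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .resources import (
    BenchmarkPairSet,
    PairScoreTable,
    PCTFPSet,
    PPINetwork,
    RegulonMap,
    ScoreThreshold,
    common_targets,
    percentile_threshold,
)
from .tf_indices import IndexResult, TF_INDEX_LABELS, evaluate_tf_indices
from .tg_indices import TG_INDEX_LABELS, build_ppi_similarity_table, evaluate_tg_indices

logger = logging.getLogger("tfcoop")

ALL_INDEX_LABELS: tuple[str, ...] = TF_INDEX_LABELS + TG_INDEX_LABELS


@dataclass
class RankingResult:
    """Sum-of-ranking-scores scheme: per-index ranks, totals, final ranking."""

    per_index_ranks: pd.DataFrame  # studies x indices, int
    totals: pd.Series              # per-study sum of ranks
    final_ranking: pd.Series       # competition ranks of totals (ascending)


@dataclass
class NormalizedResult:
    """Sum-of-normalized-scores scheme (column-max normalization)."""

    ns_matrix: pd.DataFrame  # studies x indices, in [0, 1]
    ss: pd.Series            # per-study sum of normalized scores
    final_ranking: pd.Series # competition ranks of SS (descending)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].tolist()
        raise ValueError(f"duplicate study names: {dups}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate index labels")


def rank_scores(matrix: pd.DataFrame) -> RankingResult:
    """Competition-rank each index column (1 = highest score) and sum the ranks.

    Tied scores share the minimum rank of their block, and the next
    distinct score receives min-rank + block size.  Undefined (NaN)
    entries receive the worst rank of their column, i.e. the number of
    studies.  The final ranking orders the totals ascending (smallest
    total = rank 1) with the same tie rule.
    """
    _check_matrix(matrix)
    n = len(matrix)
    fully_undefined = matrix.columns[matrix.isna().all(axis=0)].tolist()
    if fully_undefined:
        raise ValueError(f"index column(s) fully undefined: {fully_undefined}")
    ranks = matrix.rank(axis=0, method="min", ascending=False)
    ranks = ranks.fillna(float(n)).astype(int)
    totals = ranks.sum(axis=1)
    final = totals.rank(method="min", ascending=True).astype(int)
    return RankingResult(per_index_ranks=ranks, totals=totals, final_ranking=final)


def normalized_scores(matrix: pd.DataFrame) -> NormalizedResult:
    """Divide each index column by its maximum and sum across indices.

    Requires nonnegative defined scores with a positive column maximum;
    undefined entries get NS = 0.  The final ranking orders the summarized
    scores descending (largest SS = rank 1) with competition ties.
    """
    _check_matrix(matrix)
    values = matrix.astype(float)
    if (values < 0).any().any():
        bad = values.columns[(values < 0).any(axis=0)].tolist()
        raise ValueError(f"negative scores in index column(s): {bad}")
    col_max = values.max(axis=0, skipna=True)
    nonpos = col_max[~(col_max > 0)].index.tolist()
    if nonpos:
        raise ValueError(f"index column(s) with non-positive maximum: {nonpos}")
    ns = values.div(col_max, axis=1).fillna(0.0)
    ss = ns.sum(axis=1)
    final = ss.rank(method="min", ascending=False).astype(int)
    return NormalizedResult(ns_matrix=ns, ss=ss, final_ranking=final)


def ranking_correlation(
    list_a, list_b, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between two matched per-study ranking lists.

    Pearson product-moment on the rank lists by default (``method`` may be
    ``spearman`` to re-rank first); the P-value is the two-sided t-test
    with n-2 degrees of freedom.  Lists must be matched in study order.
    """
    a = np.asarray(list_a, dtype=float)
    b = np.asarray(list_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ranking lists must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 studies for a correlation test")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a ranking list")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResources:
    """Everything the eight indices need, bundled.

    ``functional`` serves both the TF-level similarity index and the
    gene-level functional-coherence index (TFs are genes).  When no
    precompiled ``ppi_sim`` table is given, one is derived from the
    network: coherence lookups over the genes that actually occur as
    common targets, and the 95th-percentile threshold from an evenly
    spaced background sample of regulon target genes (at most
    ``max_threshold_genes``), emulating a genome-wide precompiled table.
    """

    network: PPINetwork
    regulons: RegulonMap
    functional: PairScoreTable
    coexpression: PairScoreTable
    coregulation: PairScoreTable
    benchmark: BenchmarkPairSet
    universe_size: int | None = None
    universe_pair_count: int | None = None
    quantile: float = 0.95
    missing_policy: str = "exclude"
    ppi_sim: PairScoreTable | None = None
    max_threshold_genes: int = 250

    def effective_universe_size(self) -> int:
        return self.universe_size if self.universe_size is not None else self.network.universe.size

    def _background_genes(self) -> list[str]:
        pool = sorted({t for _, targets in self.regulons.items() for t in targets})
        if len(pool) <= self.max_threshold_genes:
            return pool
        step = len(pool) / self.max_threshold_genes
        return [pool[int(i * step)] for i in range(self.max_threshold_genes)]

    def ppi_sim_tables(self, sets: list[PCTFPSet]) -> tuple[PairScoreTable, PairScoreTable]:
        """(lookup table, threshold-source table) for the PPI-coherence index."""
        if self.ppi_sim is not None:
            return self.ppi_sim, self.ppi_sim
        n = self.effective_universe_size()
        needed = set()
        for s in sets:
            for pair in s.pairs:
                needed.update(common_targets(self.regulons, pair))
        lookup = build_ppi_similarity_table(self.network, needed, n)
        background = build_ppi_similarity_table(self.network, self._background_genes(), n)
        return lookup, background

    def thresholds(self, ppi_sim_background: PairScoreTable) -> dict[str, ScoreThreshold]:
        return {
            TG_INDEX_LABELS[1]: percentile_threshold(self.coexpression, self.quantile),
            TG_INDEX_LABELS[2]: percentile_threshold(self.functional, self.quantile),
            TG_INDEX_LABELS[3]: percentile_threshold(ppi_sim_background, self.quantile),
        }


@dataclass
class EvaluationReport:
    """Output of :func:`evaluate_all`: the matrix, both rankings, robustness."""

    matrix: pd.DataFrame
    ranking: RankingResult
    normalized: NormalizedResult
    correlation: dict
    index_results: dict[str, dict[str, IndexResult]] = field(default_factory=dict)
    thresholds: dict[str, ScoreThreshold] = field(default_factory=dict)


def evaluate_all(
    sets: list[PCTFPSet],
    resources: EvaluationResources,
    stat: str = "mean",
    correlation_method: str = "pearson",
) -> EvaluationReport:
    """Run all eight indices on every predicted set and build both rankings.

    Deterministic given its inputs.  The report's ``correlation`` entry is
    the cross-scheme robustness check: the Pearson correlation between the
    final rankings of the two aggregation schemes.
    """
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate PCTFP set names")
    n_universe = resources.effective_universe_size()
    pcs_lookup, pcs_background = resources.ppi_sim_tables(sets)
    thresholds = resources.thresholds(pcs_background)

    rows: dict[str, dict[str, float]] = {}
    index_results: dict[str, dict[str, IndexResult]] = {}
    for s in sets:
        try:
            tf_res = evaluate_tf_indices(
                s,
                net=resources.network,
                similarity=resources.functional,
                benchmark=resources.benchmark,
                universe_size=n_universe,
                universe_pair_count=resources.universe_pair_count,
                stat=stat,
            )
            tg_res = evaluate_tg_indices(
                s,
                regulons=resources.regulons,
                coregulation=resources.coregulation,
                coexpression=resources.coexpression,
                functional=resources.functional,
                ppi_sim=pcs_lookup,
                thresholds=thresholds,
                stat=stat,
                missing_policy=resources.missing_policy,
            )
        except Exception as exc:
            raise RuntimeError(f"evaluation failed for set {s.name!r}: {exc}") from exc
        merged = {**tf_res, **tg_res}
        index_results[s.name] = merged
        rows[s.name] = {
            label: (np.nan if merged[label].score is None else merged[label].score)
            for label in ALL_INDEX_LABELS
        }

    matrix = pd.DataFrame.from_dict(rows, orient="index").loc[names, list(ALL_INDEX_LABELS)]
    ranking = rank_scores(matrix)
    normalized = normalized_scores(matrix)
    aligned = normalized.final_ranking.loc[ranking.final_ranking.index]
    if len(sets) >= 3 and ranking.final_ranking.nunique() > 1 and aligned.nunique() > 1:
        r, p = ranking_correlation(
            ranking.final_ranking.values, aligned.values, method=correlation_method
        )
        corr = {"r": r, "p": p, "scheme": "rank_sum_vs_normalized_sum",
                "stat": stat, "method": correlation_method, "n": len(sets)}
    else:
        corr = {"r": None, "p": None, "scheme": "rank_sum_vs_normalized_sum",
                "stat": stat, "method": correlation_method, "n": len(sets),
                "note": "not computed (fewer than 3 sets or degenerate ranking)"}
    return EvaluationReport(
        matrix=matrix,
        ranking=ranking,
        normalized=normalized,
        correlation=corr,
        index_results=index_results,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# tabular output (Table-2 / Table-3 style layouts)
# ---------------------------------------------------------------------------

def _round3(df: pd.DataFrame) -> pd.DataFrame:
    # round half-even to 3 decimals for reporting; full precision kept internally
    return df.astype(float).round(3)


def rank_table(result: RankingResult) -> pd.DataFrame:
    """Rows: the eight indices, then Sum and Ranking; columns: studies."""
    out = result.per_index_ranks.T.copy()
    out.loc["Sum"] = result.totals
    out.loc["Ranking"] = result.final_ranking
    return out


def normalized_table(result: NormalizedResult) -> pd.DataFrame:
    out = _round3(result.ns_matrix.T.copy()).astype(object)
    out.loc["Sum"] = [round(v, 3) for v in result.ss]
    out.loc["Ranking"] = [int(v) for v in result.final_ranking]
    return out


def write_report(report: EvaluationReport, out_dir) -> None:
    """Write the score matrix, both ranking tables, robustness JSON and
    the per-pair score TSV into ``out_dir``."""
    from pathlib import Path

    from .resources import dump_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _round3(report.matrix).to_csv(out / "score_matrix.tsv", sep="\t")
    rank_table(report.ranking).to_csv(out / "rank_table.tsv", sep="\t")
    normalized_table(report.normalized).to_csv(out / "normalized_table.tsv", sep="\t")
    dump_json(report.correlation, out / "robustness.json")
    write_per_pair_scores(report.index_results, out / "per_pair_scores.tsv")


def write_per_pair_scores(
    index_results: dict[str, dict[str, IndexResult]], path
) -> None:
    """Per-pair score TSV: ``set  tf1  tf2  index  score  detail-json``."""
    import json

    with open(path, "w") as fh:
        fh.write("#set\ttf1\ttf2\tindex\tscore\tdetail\n")
        for set_name, per_index in index_results.items():
            for label, res in per_index.items():
                for ps in res.per_pair:
                    score = "NA" if ps.value is None else repr(round(ps.value, 6))
                    detail = dict(ps.detail)
                    if ps.reason:
                        detail["reason"] = ps.reason
                    fh.write(
                        f"{set_name}\t{ps.pair.a}\t{ps.pair.b}\t{label}\t{score}\t"
                        f"{json.dumps(detail, sort_keys=True)}\n"
                    )
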