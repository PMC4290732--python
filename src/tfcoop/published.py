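"""Published reference evaluation of 14 yeast cooperative-TF prediction algorithms.

The framework was built around a comparative evaluation of 14 published
algorithms for predicting cooperative TF pairs in S. cerevisiae.  The
final aggregation tables of that evaluation — the per-index ranking
scores and the per-index normalized scores of all 14 studies — are small
and self-contained, so they ship here as reference data.  They let users
(a) regression-test the two aggregation schemes against known output and
(b) place a new algorithm's scores alongside the published field.

Study labels follow the first author of each prediction algorithm.
"""

from __future__ import annotations

import pandas as pd

STUDIES = (
    "Banerjee", "Chang", "Chen", "Chuang", "Datta", "Elati", "Harbison",
    "He", "Nagamine", "Tsai", "WangJ", "WangY", "Yang", "Yu",
)

INDEX_ROWS = (
    "tf1_ppi_overlap",
    "tf2_shortest_path",
    "tf3_functional_similarity",
    "tf4_benchmark_overlap",
    "tg1_coregulation",
    "tg2_expression_coherence",
    "tg3_functional_coherence",
    "tg4_ppi_coherence",
)

# Per-index ranking scores (1 = best, 14 = worst) of the 14 studies.
_RANKS = (
    (6, 10, 12, 2, 5, 1, 8, 9, 7, 3, 4, 11, 14, 13),
    (9, 11, 12, 6, 8, 1, 7, 10, 2, 3, 5, 4, 14, 13),
    (2, 7, 13, 4, 9, 10, 1, 11, 8, 6, 5, 3, 14, 12),
    (6, 9, 3, 10, 12, 13, 2, 14, 7, 8, 11, 1, 4, 5),
    (5, 4, 2, 7, 12, 14, 6, 11, 8, 13, 10, 3, 1, 9),
    (7, 5, 11, 4, 3, 14, 10, 6, 9, 2, 1, 12, 13, 8),
    (6, 4, 9, 5, 3, 14, 11, 7, 10, 2, 1, 12, 13, 8),
    (6, 5, 11, 3, 4, 14, 10, 8, 7, 2, 1, 12, 13, 9),
)

# Per-index normalized scores (column-max normalization) of the 14 studies.
_NORMALIZED = (
    (0.436, 0.335, 0.286, 0.648, 0.453, 1.0, 0.408, 0.338, 0.424, 0.546, 0.493, 0.305, 0.197, 0.265),
    (0.719, 0.596, 0.582, 0.834, 0.737, 1.0, 0.797, 0.628, 0.910, 0.894, 0.840, 0.841, 0.472, 0.512),
    (0.968, 0.933, 0.740, 0.951, 0.874, 0.840, 1.0, 0.837, 0.927, 0.939, 0.947, 0.967, 0.420, 0.786),
    (0.100, 0.035, 0.247, 0.028, 0.028, 0.0, 0.315, 0.0, 0.100, 0.047, 0.028, 1.0, 0.177, 0.164),
    (0.537, 0.623, 0.732, 0.428, 0.299, 0.124, 0.465, 0.327, 0.394, 0.277, 0.345, 0.687, 1.0, 0.385),
    (0.419, 0.477, 0.279, 0.554, 0.618, 0.025, 0.283, 0.423, 0.320, 0.686, 1.0, 0.275, 0.226, 0.335),
    (0.317, 0.432, 0.293, 0.403, 0.497, 0.024, 0.275, 0.316, 0.284, 0.624, 1.0, 0.267, 0.213, 0.302),
    (0.505, 0.546, 0.407, 0.561, 0.554, 0.048, 0.411, 0.465, 0.473, 0.747, 1.0, 0.371, 0.355, 0.438),
)

# Published final ranking rows of the two aggregation schemes.
PUBLISHED_RANK_SUM_RANKING = (4, 5, 10, 3, 7, 13, 5, 11, 8, 2, 1, 8, 14, 12)
PUBLISHED_NORMALIZED_RANKING = (6, 7, 10, 4, 5, 13, 8, 11, 9, 2, 1, 3, 14, 12)


def published_rank_matrix() -> pd.DataFrame:
    """Per-index ranking scores, studies as rows, the eight indices as columns."""
    return pd.DataFrame(
        {idx: row for idx, row in zip(INDEX_ROWS, _RANKS)},
        index=list(STUDIES),
        dtype=int,
    )


def published_normalized_matrix() -> pd.DataFrame:
    """Per-index normalized scores, studies as rows, the eight indices as columns."""
    return pd.DataFrame(
        {idx: row for idx, row in zip(INDEX_ROWS, _NORMALIZED)},
        index=list(STUDIES),
        dtype=float,
    )


def rank_matrix_as_scores() -> pd.DataFrame:
    """The published per-index ranks recoded as scores (higher = better).

    Feeding this to :func:`tfcoop.aggregation.rank_scores` reproduces the
    published per-index ranks exactly (score = 15 - rank, so descending
    score order equals ascending rank order with no per-index ties).
    """
    return (15 - published_rank_matrix()).astype(float)
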