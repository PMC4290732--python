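"""Data resources for cooperative-TF-pair evaluation.

Every index in the framework consumes one of a handful of resource types:
an undirected physical protein-protein interaction (PPI) network, symmetric
gene-pair score tables (co-expression, functional similarity, co-regulatory
coefficients, PPI-overlap significance), TF regulons (TF -> target genes),
a benchmark list of known cooperative TF pairs, and the predicted
cooperative TF pair (PCTFP) sets under evaluation.

All unordered pairs share one canonical form: the lexicographically sorted
tuple ``(min(a, b), max(a, b))``.  Identifiers are compared case-sensitively
after whitespace stripping; no symbol/ORF aliasing is attempted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import yaml

logger = logging.getLogger("tfcoop")

__all__ = [
    "GeneUniverse",
    "TFPair",
    "PPINetwork",
    "PairScoreTable",
    "RegulonMap",
    "BenchmarkPairSet",
    "PCTFPSet",
    "ScoreThreshold",
    "ResourceError",
    "canonical_pair",
    "load_ppi_network",
    "write_ppi_network",
    "load_pair_score_table",
    "write_pair_score_table",
    "load_regulons",
    "write_regulons",
    "load_pair_list",
    "write_pair_list",
    "load_benchmark",
    "load_pctfp_sets",
    "percentile_threshold",
    "common_targets",
]


class ResourceError(ValueError):
    """Raised for malformed or inconsistent resource files."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (lexicographic) order.

    Raises :class:`ResourceError` for self-pairs or empty identifiers.
    """
    a = a.strip()
    b = b.strip()
    if not a or not b:
        raise ResourceError(f"empty identifier in pair ({a!r}, {b!r})")
    if a == b:
        raise ResourceError(f"self-pair ({a!r}, {b!r}) is not a valid TF pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True, order=True)
class TFPair:
    """An unordered pair of TF identifiers in canonical order (a < b)."""

    a: str
    b: str

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.a, self.b)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @classmethod
    def of(cls, a: str, b: str) -> "TFPair":
        return cls(a, b)

    def as_tuple(self) -> tuple[str, str]:
        return (self.a, self.b)

    def __iter__(self) -> Iterator[str]:
        yield self.a
        yield self.b


@dataclass(frozen=True)
class GeneUniverse:
    """The named gene universe; its size is the N of the hypergeometric tests."""

    names: frozenset[str]

    def __post_init__(self) -> None:
        if not all(isinstance(n, str) and n for n in self.names):
            raise ResourceError("universe identifiers must be non-empty strings")

    @classmethod
    def of(cls, names: Iterable[str]) -> "GeneUniverse":
        return cls(frozenset(n.strip() for n in names))

    @property
    def size(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


class PPINetwork:
    """Undirected physical-interaction graph over a named gene universe.

    Thin wrapper over a :class:`networkx.Graph` guaranteeing no self-loops
    and symmetric adjacency.  Partner sets and shortest paths are computed
    over the stored edges; proteins absent from the graph have empty
    partner sets.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], universe: GeneUniverse | None = None):
        g = nx.Graph()
        n_self = 0
        for a, b in edges:
            a, b = a.strip(), b.strip()
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
        if n_self:
            logger.info("PPINetwork: dropped %d self-edge(s)", n_self)
        self.graph = g
        self.universe = universe if universe is not None else GeneUniverse.of(g.nodes)
        self.n_self_dropped = n_self

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def partners(self, name: str) -> set[str]:
        if name not in self.graph:
            return set()
        return set(self.graph.neighbors(name))

    def degree(self, name: str) -> int:
        return self.graph.degree(name) if name in self.graph else 0

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def shortest_path_length(self, a: str, b: str) -> int | None:
        """Unweighted shortest-path edge count, or None when unreachable."""
        if a not in self.graph or b not in self.graph:
            return None
        try:
            return nx.shortest_path_length(self.graph, a, b)
        except nx.NetworkXNoPath:
            return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.edge_set() == other.edge_set()

    def __repr__(self) -> str:
        return f"PPINetwork({self.graph.number_of_nodes()} nodes, {self.n_edges} edges)"


class PairScoreTable:
    """Symmetric lookup from canonical unordered pairs to a finite score."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None,
                 description: str = ""):
        self._entries: dict[tuple[str, str], float] = {}
        self.description = description
        if entries:
            for (a, b), s in entries.items():
                self.set(a, b, float(s))

    def set(self, a: str, b: str, score: float) -> None:
        if not math.isfinite(score):
            raise ResourceError(f"non-finite score {score!r} for pair ({a}, {b})")
        self._entries[canonical_pair(a, b)] = float(score)

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._entries.get(canonical_pair(a, b), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._entries.items())

    def scores(self) -> list[float]:
        return list(self._entries.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairScoreTable):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        d = f", {self.description!r}" if self.description else ""
        return f"PairScoreTable({len(self)} pairs{d})"


class RegulonMap:
    """TF -> set of target genes.  Lookup is total: absent TFs give the empty set."""

    def __init__(self, regulons: Mapping[str, Iterable[str]] | None = None):
        self._regulons: dict[str, set[str]] = {}
        if regulons:
            for tf, targets in regulons.items():
                self.add(tf, targets)

    def add(self, tf: str, targets: Iterable[str]) -> None:
        tf = tf.strip()
        self._regulons.setdefault(tf, set()).update(t.strip() for t in targets)

    def targets(self, tf: str) -> set[str]:
        return set(self._regulons.get(tf.strip(), set()))

    @property
    def tfs(self) -> set[str]:
        return set(self._regulons)

    def items(self) -> Iterator[tuple[str, set[str]]]:
        return iter(self._regulons.items())

    def __len__(self) -> int:
        return len(self._regulons)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulonMap):
            return NotImplemented
        return self._regulons == other._regulons


@dataclass
class BenchmarkPairSet:
    """Known cooperative TF pairs against which predicted sets are tested."""

    pairs: frozenset[TFPair]
    tf_universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.tf_universe:
            self.tf_universe = frozenset(t for p in self.pairs for t in p)
        missing = {t for p in self.pairs for t in p} - set(self.tf_universe)
        if missing:
            raise ResourceError(f"benchmark pairs use TFs outside the TF universe: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PCTFPSet:
    """A named algorithm's list of predicted cooperative TF pairs."""

    name: str
    pairs: list[TFPair]

    def __post_init__(self) -> None:
        seen: set[TFPair] = set()
        deduped: list[TFPair] = []
        for p in self.pairs:
            if p not in seen:
                seen.add(p)
                deduped.append(p)
        n_dup = len(self.pairs) - len(deduped)
        if n_dup:
            logger.info("PCTFPSet %s: collapsed %d duplicate pair(s)", self.name, n_dup)
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> set[TFPair]:
        return set(self.pairs)


@dataclass(frozen=True)
class ScoreThreshold:
    """A nearest-rank percentile threshold; ``value`` is an attained score."""

    value: float
    quantile: float
    source_size: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (line_number, fields) for non-blank, non-comment TSV lines."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line.split("\t")


def load_ppi_network(
    path: str | Path,
    dialect: str = "simple_tsv",
    physical_only: bool = False,
    interactor_cols: tuple[int, int] = (0, 1),
    category_col: int = 2,
    universe: GeneUniverse | None = None,
) -> PPINetwork:
    """Read an undirected PPI edge list.

    ``simple_tsv`` is a two-column edge list (header starting with ``#``
    or stray extra columns tolerated).  ``biogrid_tab`` is a tab-delimited
    dialect with configurable column indices for the two interactor-symbol
    columns and the experimental-category column; with ``physical_only``
    set, rows whose category is not ``physical`` are skipped.

    Duplicate and reversed edges are collapsed; self-edges are dropped
    with a logged count.
    """
    if dialect not in ("simple_tsv", "biogrid_tab"):
        raise ResourceError(f"unknown PPI dialect {dialect!r}")
    edges: list[tuple[str, str]] = []
    for lineno, fields in _data_lines(path):
        if dialect == "simple_tsv":
            if len(fields) < 2:
                raise ResourceError(f"{path}:{lineno}: expected 2 tab-separated columns")
            a, b = fields[0], fields[1]
        else:
            needed = max(*interactor_cols, category_col if physical_only else 0)
            if len(fields) <= needed:
                raise ResourceError(f"{path}:{lineno}: expected at least {needed + 1} columns")
            if physical_only and fields[category_col].strip().lower() != "physical":
                continue
            a, b = fields[interactor_cols[0]], fields[interactor_cols[1]]
        if not a.strip() or not b.strip():
            raise ResourceError(f"{path}:{lineno}: empty interactor identifier")
        edges.append((a, b))
    if not edges:
        raise ResourceError(f"{path}: no edges parsed")
    return PPINetwork(edges, universe=universe)


def write_ppi_network(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for a, b in sorted(net.edge_set()):
            fh.write(f"{a}\t{b}\n")


def load_pair_score_table(
    path: str | Path, dedup: str = "keep_max", description: str = ""
) -> PairScoreTable:
    """Read a three-column TSV ``id1<TAB>id2<TAB>score`` into a symmetric table.

    Duplicate unordered keys are resolved per ``dedup``: ``keep_max``
    (default, with a logged count) or ``error``.
    """
    if dedup not in ("keep_max", "error"):
        raise ResourceError(f"unknown dedup policy {dedup!r}")
    table = PairScoreTable(description=description or str(path))
    n_dup = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ResourceError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            score = float(fields[2])
        except ValueError:
            raise ResourceError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from None
        prev = table.get(fields[0], fields[1])
        if prev is not None:
            if dedup == "error":
                raise ResourceError(f"{path}:{lineno}: duplicate pair ({fields[0]}, {fields[1]})")
            n_dup += 1
            score = max(prev, score)
        table.set(fields[0], fields[1], score)
    if len(table) == 0:
        raise ResourceError(f"{path}: empty score table")
    if n_dup:
        logger.warning("%s: %d duplicate pair(s) resolved with keep_max", path, n_dup)
    return table


def write_pair_score_table(table: PairScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (a, b), s in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{s!r}\n")


def load_regulons(path: str | Path, dialect: str = "two_col_tsv") -> RegulonMap:
    """Read a TF -> targets map from ``two_col_tsv`` (tf<TAB>target rows) or
    ``gmt`` (name<TAB>description<TAB>member...) files."""
    if dialect not in ("two_col_tsv", "gmt"):
        raise ResourceError(f"unknown regulon dialect {dialect!r}")
    regulons = RegulonMap()
    for lineno, fields in _data_lines(path):
        if dialect == "two_col_tsv":
            if len(fields) < 2:
                raise ResourceError(f"{path}:{lineno}: expected 2 tab-separated columns")
            regulons.add(fields[0], [fields[1]])
        else:
            if len(fields) < 3:
                raise ResourceError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            regulons.add(fields[0], fields[2:])
    return regulons


def write_regulons(regulons: RegulonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#tf\ttarget\n")
        for tf, targets in sorted(regulons.items()):
            for t in sorted(targets):
                fh.write(f"{tf}\t{t}\n")


def load_pair_list(path: str | Path) -> list[TFPair]:
    """Read a two-column TSV of TF pairs, canonicalized, duplicates collapsed."""
    pairs: list[TFPair] = []
    seen: set[TFPair] = set()
    n_dup = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ResourceError(f"{path}:{lineno}: expected 2 tab-separated columns")
        p = TFPair(fields[0], fields[1])
        if p in seen:
            n_dup += 1
            continue
        seen.add(p)
        pairs.append(p)
    if not pairs:
        raise ResourceError(f"{path}: no TF pairs parsed")
    if n_dup:
        logger.info("%s: collapsed %d duplicate pair(s)", path, n_dup)
    return pairs


def write_pair_list(pairs: Iterable[TFPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#tf1\ttf2\n")
        for p in pairs:
            fh.write(f"{p.a}\t{p.b}\n")


def load_name_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line list (comments and blanks skipped)."""
    names: list[str] = []
    for _, fields in _data_lines(path):
        names.append(fields[0].strip())
    return names


def write_name_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in names:
            fh.write(f"{n}\n")


def load_benchmark(path: str | Path, tf_universe: Iterable[str] | None = None) -> BenchmarkPairSet:
    pairs = frozenset(load_pair_list(path))
    universe = frozenset(t.strip() for t in tf_universe) if tf_universe else frozenset()
    return BenchmarkPairSet(pairs=pairs, tf_universe=universe)


def load_pctfp_sets(manifest: str | Path) -> list[PCTFPSet]:
    """Load the predicted sets listed in a YAML/JSON manifest.

    The manifest is either a list of ``{name, path}`` entries or a mapping
    with a ``sets`` key holding such a list.  Paths are resolved relative
    to the manifest's directory.  Duplicate set names and missing files
    are errors.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("sets") if isinstance(doc, dict) else doc
    if not isinstance(entries, list) or not entries:
        raise ResourceError(f"{manifest}: manifest lists no PCTFP sets")
    sets: list[PCTFPSet] = []
    names: set[str] = set()
    for entry in entries:
        name, rel = entry["name"], entry["path"]
        if name in names:
            raise ResourceError(f"{manifest}: duplicate set name {name!r}")
        names.add(name)
        path = Path(rel)
        if not path.is_absolute():
            path = manifest.parent / path
        if not path.exists():
            raise ResourceError(f"{manifest}: listed file {path} does not exist")
        sets.append(PCTFPSet(name=name, pairs=load_pair_list(path)))
    return sets


# ---------------------------------------------------------------------------
# shared utilities
# ---------------------------------------------------------------------------

def percentile_threshold(table: PairScoreTable, quantile: float) -> ScoreThreshold:
    """Nearest-rank percentile of a score table.

    Scores are sorted ascending and the value at 1-based position
    ``ceil(quantile * n)`` is returned, so the threshold is always an
    attained score.
    """
    if not 0 < quantile < 1:
        raise ResourceError(f"quantile must lie in (0, 1), got {quantile}")
    n = len(table)
    if n == 0:
        raise ResourceError("cannot take a percentile of an empty score table")
    ordered = sorted(table.scores())
    rank = math.ceil(quantile * n)  # 1-based nearest-rank
    return ScoreThreshold(value=ordered[rank - 1], quantile=quantile, source_size=n)


def common_targets(regulons: RegulonMap, pair: TFPair) -> set[str]:
    """Intersection of the two regulons; empty when either TF is absent."""
    return regulons.targets(pair.a) & regulons.targets(pair.b)


def dump_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
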