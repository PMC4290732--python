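"""Seeded synthetic resource worlds with planted cooperative structure.

The generator emulates the statistical structure the eight indices assume,
at a desk scale (default 1000 genes, 60 TFs):

* a background physical PPI network with independent edges at a fixed
  density, on top of which each *planted* cooperative TF pair is wired to
  a shared block of interaction partners and, with some probability,
  directly to each other, emulating complex formation (signal for the
  partner-overlap and shortest-path indices);
* random regulons, with each planted pair sharing a core of common target
  genes (signal for the co-regulation index), whose gene pairs draw their
  co-expression and functional-similarity scores from a *coherent*
  distribution while all other scored pairs draw from a *null*
  distribution (signal for the expression/functional coherence indices);
  core genes are additionally wired into the pair's shared partner block
  (signal for the PPI-coherence index);
* a benchmark that is a random subset of the planted pairs (signal for
  the benchmark-overlap index).

Score distributions default to Beta(2, 8) for null and Beta(8, 2) for
coherent pairs — clearly separated but overlapping.  The co-regulation
table is not drawn independently: it is the hypergeometric -log10
significance of the realized regulon overlaps, so its signal is
consistent with the regulons.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .aggregation import EvaluationResources
from .resources import (
    BenchmarkPairSet,
    GeneUniverse,
    PairScoreTable,
    PCTFPSet,
    PPINetwork,
    RegulonMap,
    TFPair,
    write_name_list,
    write_pair_list,
    write_pair_score_table,
    write_ppi_network,
    write_regulons,
)
from .tf_indices import hypergeom_overlap_scores


@dataclass
class WorldParams:
    """Knobs of the synthetic world; defaults are the standard test scale."""

    n_genes: int = 1000              # total universe size, TFs included
    n_tfs: int = 60
    ppi_density: float = 0.005       # background edge probability
    n_planted_pairs: int = 40
    planted_partner_overlap: float = 0.5   # fraction of each partner block shared
    partner_block_size: int = 20     # extra PPI partners wired per planted TF
    planted_direct_edge_prob: float = 0.5  # chance a planted pair interacts directly
    regulon_size: tuple[int, int] = (20, 50)   # inclusive range, drawn uniformly
    planted_target_overlap: float = 0.5        # shared-core fraction of min regulon
    score_null: tuple[float, float] = (2.0, 8.0)      # Beta(a, b) for null pairs
    score_coherent: tuple[float, float] = (8.0, 2.0)  # Beta(a, b) for coherent pairs
    benchmark_fraction: float = 0.5
    n_background_pairs: int = 150    # non-planted TF pairs kept as a sampling pool
    n_null_score_pairs: int = 50000  # extra random gene pairs per score table
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_tfs, self.partner_block_size) <= 0:
            raise ValueError("counts must be positive")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        for name in ("ppi_density", "planted_partner_overlap", "planted_direct_edge_prob",
                     "planted_target_overlap", "benchmark_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.regulon_size
        if not 0 < lo <= hi:
            raise ValueError(f"invalid regulon_size range {self.regulon_size}")
        max_pairs = self.n_tfs * (self.n_tfs - 1) // 2
        if self.n_planted_pairs + self.n_background_pairs > max_pairs:
            raise ValueError("planted + background pairs exceed the number of TF pairs")
        if round(self.planted_target_overlap * lo) > self.n_genes - self.n_tfs:
            raise ValueError("planted target overlap exceeds the target-gene pool")
        a_n, b_n = self.score_null
        a_c, b_c = self.score_coherent
        if a_c / (a_c + b_c) <= a_n / (a_n + b_n):
            raise ValueError("coherent score distribution must dominate the null")


@dataclass
class SyntheticWorld:
    """A complete, internally consistent set of evaluation resources."""

    params: WorldParams
    universe: GeneUniverse
    tfs: list[str]
    network: PPINetwork
    regulons: RegulonMap
    coexpression: PairScoreTable
    functional: PairScoreTable
    coregulation: PairScoreTable
    benchmark: BenchmarkPairSet
    planted_pairs: list[TFPair]
    background_pairs: list[TFPair]
    planted_cores: dict[TFPair, frozenset[str]] = field(default_factory=dict)

    def resources(self, quantile: float = 0.95, missing_policy: str = "exclude") -> EvaluationResources:
        return EvaluationResources(
            network=self.network,
            regulons=self.regulons,
            functional=self.functional,
            coexpression=self.coexpression,
            coregulation=self.coregulation,
            benchmark=self.benchmark,
            universe_size=self.params.n_genes,
            universe_pair_count=self.params.n_tfs * (self.params.n_tfs - 1) // 2,
            quantile=quantile,
            missing_policy=missing_policy,
        )


def _tf_name(i: int) -> str:
    return f"TF{i + 1:03d}"


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Build a synthetic world from ``params``; fully reproducible from the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params

    tfs = [_tf_name(i) for i in range(p.n_tfs)]
    target_genes = [_gene_name(i) for i in range(p.n_genes - p.n_tfs)]
    all_names = tfs + target_genes
    universe = GeneUniverse.of(all_names)

    # --- background PPI: independent edges at ppi_density --------------------
    n = p.n_genes
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p.ppi_density
    edges: set[tuple[str, str]] = set()
    for i, j in zip(iu[mask], ju[mask]):
        a, b = all_names[i], all_names[j]
        edges.add((a, b) if a < b else (b, a))

    # --- planted TF pairs and their shared partner blocks --------------------
    all_tf_pairs = list(combinations(tfs, 2))
    order = rng.permutation(len(all_tf_pairs))
    planted_pairs = [TFPair(*all_tf_pairs[k]) for k in order[: p.n_planted_pairs]]
    background_pairs = [
        TFPair(*all_tf_pairs[k])
        for k in order[p.n_planted_pairs : p.n_planted_pairs + p.n_background_pairs]
    ]

    # cooperative TFs frequently interact directly (complex formation)
    for pair in planted_pairs:
        if rng.random() < p.planted_direct_edge_prob:
            edges.add(pair.as_tuple())

    n_shared = round(p.planted_partner_overlap * p.partner_block_size)
    n_own = p.partner_block_size - n_shared
    shared_blocks: dict[TFPair, list[str]] = {}
    for pair in planted_pairs:
        pool = [g for g in target_genes]  # blocks drawn from non-TF genes
        block = rng.choice(len(pool), size=n_shared + 2 * n_own, replace=False)
        chosen = [pool[k] for k in block]
        shared = chosen[:n_shared]
        own_a, own_b = chosen[n_shared : n_shared + n_own], chosen[n_shared + n_own :]
        shared_blocks[pair] = shared
        for g in shared + own_a:
            edges.add((pair.a, g) if pair.a < g else (g, pair.a))
        for g in shared + own_b:
            edges.add((pair.b, g) if pair.b < g else (g, pair.b))

    # --- regulons with planted common-target cores ---------------------------
    # Cores are drawn first and count toward each TF's drawn regulon size, so
    # a planted pair's common-target count is at least
    # ceil(planted_target_overlap * min drawn size) by construction.
    lo, hi = p.regulon_size
    sizes = {tf: int(rng.integers(lo, hi + 1)) for tf in tfs}
    planted_cores: dict[TFPair, frozenset[str]] = {}
    core_union: dict[str, set[str]] = {tf: set() for tf in tfs}
    for pair in planted_pairs:
        k = math.ceil(p.planted_target_overlap * min(sizes[pair.a], sizes[pair.b]))
        idx = rng.choice(len(target_genes), size=k, replace=False)
        core = frozenset(target_genes[j] for j in idx)
        planted_cores[pair] = core
        core_union[pair.a] |= core
        core_union[pair.b] |= core
        # wire core genes into the pair's shared partner block (PPI coherence)
        block = shared_blocks[pair]
        n_wire = max(1, math.ceil(len(block) / 2)) if block else 0
        for g in sorted(core):
            if n_wire:
                pick = rng.choice(len(block), size=min(n_wire, len(block)), replace=False)
                for j in pick:
                    h = block[j]
                    if g != h:
                        edges.add((g, h) if g < h else (h, g))

    regulons = RegulonMap()
    reg_sets: dict[str, set[str]] = {}
    for tf in tfs:
        required = set(core_union[tf])
        need = sizes[tf] - len(required)
        if need > 0:
            candidates = [g for g in target_genes if g not in required]
            idx = rng.choice(len(candidates), size=need, replace=False)
            required |= {candidates[j] for j in idx}
        reg_sets[tf] = required
        regulons.add(tf, required)

    network = PPINetwork(sorted(edges), universe=universe)

    # --- gene-pair score tables ----------------------------------------------
    coherent_gene_pairs: set[tuple[str, str]] = set()
    for core in planted_cores.values():
        for a, b in combinations(sorted(core), 2):
            coherent_gene_pairs.add((a, b))

    scored_pairs: set[tuple[str, str]] = set()
    for tf in tfs:
        for a, b in combinations(sorted(reg_sets[tf]), 2):
            scored_pairs.add((a, b))
    n_extra = p.n_null_score_pairs
    ii = rng.integers(0, len(target_genes), size=2 * n_extra)
    jj = rng.integers(0, len(target_genes), size=2 * n_extra)
    added = 0
    for i, j in zip(ii, jj):
        if added >= n_extra:
            break
        if i == j:
            continue
        a, b = target_genes[i], target_genes[j]
        key = (a, b) if a < b else (b, a)
        if key not in scored_pairs:
            scored_pairs.add(key)
            added += 1

    def draw_table(description: str) -> PairScoreTable:
        keys = sorted(scored_pairs)
        is_coherent = np.array([k in coherent_gene_pairs for k in keys])
        a_n, b_n = p.score_null
        a_c, b_c = p.score_coherent
        vals = rng.beta(a_n, b_n, size=len(keys))
        if is_coherent.any():
            vals[is_coherent] = rng.beta(a_c, b_c, size=int(is_coherent.sum()))
        table = PairScoreTable(description=description)
        for (a, b), v in zip(keys, vals):
            table.set(a, b, float(v))
        return table

    coexpression = draw_table("synthetic co-expression")
    functional = draw_table("synthetic functional similarity")

    # TF-level functional similarity entries (the TF pair itself, index 3)
    planted_set = set(planted_pairs)
    a_n, b_n = p.score_null
    a_c, b_c = p.score_coherent
    for pair_tuple in all_tf_pairs:
        pair = TFPair(*pair_tuple)
        if pair in planted_set:
            functional.set(pair.a, pair.b, float(rng.beta(a_c, b_c)))
        else:
            functional.set(pair.a, pair.b, float(rng.beta(a_n, b_n)))

    # --- co-regulation: hypergeometric significance of realized overlaps -----
    n_pool = len(target_genes)
    pairs_arr = [TFPair(*t) for t in all_tf_pairs]
    c = np.array([len(reg_sets[q.a] & reg_sets[q.b]) for q in pairs_arr])
    n1 = np.array([len(reg_sets[q.a]) for q in pairs_arr])
    n2 = np.array([len(reg_sets[q.b]) for q in pairs_arr])
    scores = hypergeom_overlap_scores(c, n_pool, n1, n2)
    coregulation = PairScoreTable(description="synthetic co-regulation coefficients")
    for q, s in zip(pairs_arr, scores):
        if s > 0:  # the co-regulatory network keeps only observed associations
            coregulation.set(q.a, q.b, float(s))

    # --- benchmark: a random subset of the planted pairs ---------------------
    n_bench = round(p.benchmark_fraction * len(planted_pairs))
    pick = rng.choice(len(planted_pairs), size=n_bench, replace=False)
    benchmark = BenchmarkPairSet(
        pairs=frozenset(planted_pairs[k] for k in pick),
        tf_universe=frozenset(tfs),
    )

    return SyntheticWorld(
        params=p,
        universe=universe,
        tfs=tfs,
        network=network,
        regulons=regulons,
        coexpression=coexpression,
        functional=functional,
        coregulation=coregulation,
        benchmark=benchmark,
        planted_pairs=planted_pairs,
        background_pairs=background_pairs,
        planted_cores=planted_cores,
    )


def generate_pctfp_sets(
    world: SyntheticWorld,
    qualities: list[float],
    n_pairs: int,
    seed: int,
) -> list[PCTFPSet]:
    """Predicted sets of controlled quality.

    Set k holds ``round(qualities[k] * n_pairs)`` planted pairs and the
    remainder random background pairs, sampled without replacement from
    the world's pools.  Set names encode the quality.
    """
    rng = np.random.default_rng(seed)
    sets: list[PCTFPSet] = []
    for i, q in enumerate(qualities):
        if not 0 <= q <= 1:
            raise ValueError(f"quality must lie in [0, 1], got {q}")
        k = round(q * n_pairs)
        if k > len(world.planted_pairs):
            raise ValueError(
                f"need {k} planted pairs but the world has {len(world.planted_pairs)}"
            )
        if n_pairs - k > len(world.background_pairs):
            raise ValueError(
                f"need {n_pairs - k} background pairs but the world has "
                f"{len(world.background_pairs)}"
            )
        planted_idx = rng.choice(len(world.planted_pairs), size=k, replace=False)
        background_idx = rng.choice(len(world.background_pairs), size=n_pairs - k, replace=False)
        pairs = [world.planted_pairs[j] for j in planted_idx] + [
            world.background_pairs[j] for j in background_idx
        ]
        sets.append(PCTFPSet(name=f"set{i + 1}_q{int(round(q * 100)):03d}", pairs=pairs))
    return sets


def write_world(
    world: SyntheticWorld,
    out_dir: str | Path,
    sets: list[PCTFPSet] | None = None,
) -> Path:
    """Serialize all resources (plus optional predicted sets) to a directory.

    Output uses the standard text formats of :mod:`tfcoop.resources` and a
    ``manifest.yaml`` consumable by the ``evaluate`` command.  Returns the
    manifest path.  Byte-identical for identical worlds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ppi_network(world.network, out / "ppi.tsv")
    write_regulons(world.regulons, out / "regulons.tsv")
    write_pair_score_table(world.coexpression, out / "coexpression.tsv")
    write_pair_score_table(world.functional, out / "functional.tsv")
    write_pair_score_table(world.coregulation, out / "coregulation.tsv")
    write_pair_list(sorted(world.benchmark.pairs), out / "benchmark.tsv")
    write_name_list(world.tfs, out / "tf_universe.tsv")
    write_pair_list(world.planted_pairs, out / "planted_pairs.tsv")
    write_pair_list(world.background_pairs, out / "background_pairs.tsv")

    manifest: dict = {
        "resources": {
            "ppi": "ppi.tsv",
            "regulons": "regulons.tsv",
            "coexpression": "coexpression.tsv",
            "functional": "functional.tsv",
            "coregulation": "coregulation.tsv",
            "benchmark": "benchmark.tsv",
            "tf_universe": "tf_universe.tsv",
        },
        "options": {
            "universe_size": world.params.n_genes,
            "universe_pair_count": world.params.n_tfs * (world.params.n_tfs - 1) // 2,
            "tf_universe_size": world.params.n_tfs,
        },
        "sets": [],
    }
    if sets:
        (out / "sets").mkdir(exist_ok=True)
        for s in sets:
            rel = f"sets/{s.name}.tsv"
            write_pair_list(s.pairs, out / rel)
            manifest["sets"].append({"name": s.name, "path": rel})
    with open(out / "params.json", "w") as fh:
        params = {k: list(v) if isinstance(v, tuple) else v
                  for k, v in vars(world.params).items()}
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
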