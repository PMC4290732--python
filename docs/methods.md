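# Methods

## Scope and model

`tfcoop` evaluates sets of predicted cooperative TF pairs (PCTFPs)
against eight independent evidence channels and aggregates the results
into comprehensive rankings. It does not predict cooperativity itself and
does not recompute the upstream resources it consumes: co-expression,
functional-similarity and co-regulatory coefficients enter as precomputed
pair-score tables, exactly as a user would export them from SPELL-style
compendia, GO semantic-similarity studies, or a co-regulatory network.
Regulons (TF → target genes) and the physical PPI network are read from
plain text files.

All unordered pairs — TF pairs, gene pairs, network edges — share one
canonical form, the lexicographically sorted tuple, so every lookup is
symmetric by construction. Identifiers are compared case-sensitively
after whitespace stripping; no ORF/symbol aliasing is attempted.

## The indices

**Partner-overlap significance (TF index 1, and the kernel of PCS).**
For a pair with partner sets of sizes `N1`, `N2` sharing `c` partners in
a universe of `N` genes, the score is `−log10` of the upper hypergeometric
tail `P(X ≥ c)`. `scipy.stats.hypergeom.sf` supplies the tail; the test
suite checks it against exhaustive subset enumeration (all placements of
the second partner set) to 1e−12 for universes up to 12. The default
universe is `N = 6575` unique yeast genes; for synthetic worlds it is the
world's gene count. A TF absent from the network has an empty partner
set, hence `c = 0`, `P = 1`, score 0. P-values are floored at 1e−300
before logs, so scores are finite; logarithms are base 10 throughout.

**Shortest path (TF index 2).** `S = 1/L` with `L` the unweighted
breadth-first shortest-path length. Unreachable or absent TFs score 0,
the limit of `1/L` as `L` grows — this keeps the score defined for every
pair rather than dropping disconnected ones.

**Functional similarity (TF index 3).** Pure table lookup. Pairs absent
from the table are *undefined* and excluded from the set summary (with
counts logged), not zero-filled: absence means unmeasured, and zero
filling would conflate unmeasured with dissimilar. A `missing_policy`
switch preserves the alternative reading where relevant downstream.

**Benchmark overlap (TF index 4).** One-sided (enrichment) Fisher exact
test of the predicted set against the benchmark over a universe of
possible TF pairs. The TF universe defaults to the TFs appearing in the
benchmark resource and is configurable (the synthetic manifests name the
full TF universe explicitly); predicted pairs outside it are dropped with
a logged count. The score is `−log10(P)`. This is the only set-level
index; the other seven are per-pair scores summarized by mean or median.

**Co-regulation (TG index 1).** Table lookup; pairs absent from the
coefficient table score 0 rather than undefined, because a co-regulatory
network records only significant associations — absence is itself the
measurement.

**Coherence scores ECS/FCS/PCS (TG indices 2–4).** For the `m` common
target genes of a pair, all `C(m, 2)` gene pairs are formed and the score
is the fraction lying *strictly above* a global threshold (ties at the
threshold do not count, following the "higher than" definition). The
threshold is the nearest-rank 95th percentile of the full backing table:
sort ascending, take the value at 1-based position `ceil(0.95 · n)` — a
nearest-rank form so the threshold is always an attained score; no
interpolation rule is assumed. Gene pairs absent from the table are
excluded from numerator and denominator (same rationale and switch as
index 3). Pairs with fewer than two common targets, or with no scored
gene pair, are undefined and excluded from the set summary. PCS uses the
same partner-overlap kernel as TF index 1 through one shared
implementation; `build_ppi_similarity_table` batches it with a sparse
matrix product for the common-partner counts and one vectorized tail
call. When no precompiled PCS table is supplied, coherence lookups are
computed over the genes that actually occur as common targets, while the
threshold comes from an evenly spaced background sample of regulon target
genes (at most 250, ~31k pairs), standing in for a genome-wide
precompiled table deterministically.

## Aggregation

Ranks use competition (minimum) ranking: tied scores share the smallest
rank of their block and the following distinct value skips accordingly.
This is the tie rule consistent with the published reference tables,
where two studies with rank-sum 55 both hold final rank 5 and ranks 6 and
9 are skipped. Undefined matrix entries receive the worst rank of their
column (the number of studies) in the rank-sum scheme and NS = 0 in the
normalized scheme — deliberately conservative penalties; complete
matrices are unaffected. Normalization requires nonnegative scores with
a positive column maximum and errors otherwise, naming the index.

The robustness correlation is a Pearson product-moment correlation of the
two integer rank lists, with the two-sided P-value from the t statistic
`r·sqrt((n−2)/(1−r²))` on `n−2` degrees of freedom. Pearson on rank lists
(rather than Spearman re-ranking) reproduces the published cross-scheme
value of 0.90 and its printed P-value; the estimator is switchable.
Reported tables round half-even to 3 decimals; full precision is kept
internally (so a Sum column may differ from the sum of its printed
components by one unit in the last place).

## Synthetic worlds

The generator builds a complete, internally consistent resource world at
a desk scale, defaulting to 1000 genes of which 60 are TFs, with 40
planted cooperative pairs:

* **PPI**: independent background edges at density 0.005 (mean degree
  ≈ 5, a sparse giant component). Each planted pair is wired to a partner
  block of 20 genes per TF, of which half are shared, and with
  probability 0.5 the two TFs are joined directly — cooperative TFs
  frequently form physical complexes, and this is what gives the
  shortest-path index its signal.
* **Regulons**: sizes uniform in [20, 50]. Each planted pair first draws
  a common-target core of `ceil(0.5 · min(size_a, size_b))` genes counted
  toward both regulons, so the realized common-target count is at least
  half the minimum drawn regulon size by construction.
* **Score tables**: co-expression and functional similarity cover all
  within-regulon gene pairs plus 50k random background pairs (enough to
  pin the 95th percentile); pairs inside a planted core draw from
  Beta(8, 2), all others from Beta(2, 8) — clearly separated but
  overlapping distributions. TF-level functional similarity is drawn the
  same way (coherent for planted pairs).
* **Co-regulation**: not drawn independently — it is the hypergeometric
  `−log10` significance of the realized regulon overlaps (entries kept
  when positive), so TG index 1's signal is consistent with the regulons.
* **PPI coherence signal**: each core gene is wired to a random half of
  its pair's shared partner block, so core gene pairs share partners.
* **Benchmark**: a random half of the planted pairs, over the full TF
  universe.

Everything derives from one `numpy` generator seeded by `WorldParams.seed`;
serialized worlds are byte-identical across runs with equal parameters.
`generate_pctfp_sets` assembles predicted sets of controlled quality
(planted fraction), which the full pipeline should — and, in the test
suite, does — rank in quality order under both aggregation schemes.

What the generator does **not** emulate: yeast network topology
(scale-free degree distributions, modularity), correlated noise between
evidence channels, regulon size distributions of real TFs, or incomplete
measurement (tables cover every within-regulon pair). Passing the
recovery tests therefore demonstrates that the indices detect the kinds
of signal they were designed for, not that they are calibrated for any
particular real data release.

## Numerical and design choices

* Hypergeometric/Fisher universes smaller than the observed margins are
  hard errors (impossible configurations), not clamped.
* The BioGRID-style reader's column indices and "physical" category
  filter are configurable, since tab-dialect releases differ.
* Duplicate entries in score tables resolve to the maximum with a
  warning by default (an `error` policy is available).
* Percentile thresholds, coherence denominators and tie rules are exactly
  as above; none depend on input ordering, and all loaders canonicalize
  pair orientation, so loading a file with every pair reversed yields an
  identical object.
* Test problem sizes: oracle enumerations run at universes ≤ 12 and
  graphs ≤ 10 nodes, where exhaustive enumeration is exact and fast;
  synthetic recovery runs at the default 1000-gene scale over 10 seeds.

## Known limitations

* No ORF/symbol aliasing: resources must agree on identifiers.
* The Fisher-universe construction for the benchmark index admits several
  readings; the TF universe and pair count are configurable rather than
  fixed.
* Index scores of real prediction sets depend on the releases of the
  backing databases; the package deliberately pins nothing and treats all
  resources as user-supplied inputs.
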