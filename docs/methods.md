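# Methods

## Model

`kinconn` scores the association between a query kinase set and each
drug of a reference database of quantitative kinase-inhibitor activity
profiles. The statistic is the rank-based, signed Kolmogorov–Smirnov
enrichment measure of connectivity mapping: only the *positions* of the
query kinases within each drug's rank-ordered profile matter, never the
raw measured values, which makes the score invariant under any strictly
monotone transform of the measurements (log-K<sub>d</sub> vs
K<sub>d</sub>, different assay scales) and applicable across assay
technologies.

Two database kinds are supported and handled identically after
ranking: percent kinase inhibition (values in [0, 100], higher = more
potent) and dissociation constants K<sub>d</sub> in μM (values > 0,
lower = more potent). Rank 1 is always the most potent interaction, so
a positive score means "this drug concentrates its potency on the
query kinases".

For a drug with an N-kinase profile and M matched query kinases at
sorted ranks R₁ ≤ … ≤ R_M:

- a = max_j (j/M − R_j/N), b = max_j (R_j/N − (j−1)/M);
- KS = a if a > b, −b if b > a;
- across drugs, P = max KS and Q = min KS, S = KS/P (KS > 0) or −KS/Q
  (KS < 0);
- final ranking by the normalized score (S + 1)/2;
- running sum D(r) = hits(r)/M − r/N, whose maximum equals a exactly
  (the j = M term forces a ≥ 0 whenever all query kinases are ranked,
  and D attains its maxima only at hit positions).

Note the asymmetry inherited from the j-index conventions: a compares
against j/M while b compares against (j−1)/M, so b > 0 strictly for any
nonempty query while a ≥ 0.

## Numerical choices

- **Exact tie arithmetic.** a and b are rational with common
  denominator M·N; both the scalar path and the vectorized permutation
  path compare integer numerators (j·N − R_j·M etc.), so the a vs b
  branch is decided exactly rather than at float precision. The same
  values divided at the end give the returned floats.
- **a == b tie** takes the positive branch (KS = a). The case rule only
  covers strict inequalities; the tie set has measure zero on
  continuous measurements but is reachable on integer rank grids, so it
  must be fixed deterministically. The positive branch follows the
  enrichment-favoring convention of connectivity mapping.
- **KS = 0 maps to S = 0** (the rescaling rule covers only KS ≠ 0).
- **0–1 normalization** is the affine map (S + 1)/2: order-preserving,
  sign-recoverable (0.5 is the neutral point), and exactly onto [0, 1]
  given S ∈ [−1, 1]. Any strictly increasing map would rank
  identically; this one is documented because the choice is free.
- **Ties in activity values** are broken by ascending kinase symbol
  (bytewise on the uppercased string). Average/fractional ranks are not
  used because the formulas require integer ranks forming a permutation
  of 1..N.
- **Final-table ties** (equal normalized score) break by ascending drug
  id, so output is reproducible.

## Missing data policy

Reference panels differ in kinase coverage, so N is per-drug (N_i =
number of kinases actually assayed for drug i). Query kinases absent
from a drug's panel are dropped from that drug's query, M becomes the
per-drug match count (`n_matched`, reported per row so users can
filter), and drugs matching no query kinase are listed in a separate
unscored section rather than being scored or silently dropped. Padding
unassayed kinases with worst ranks was rejected: it would fabricate
negative evidence about measurements that were never made.

## Permutation test

The null redraws the query as a uniform random M-subset of the drug's
ranks 1..N without replacement (a query cannot contain a kinase
twice), recomputes KS for each of T trials (default T = 500), and
reports p = f/T.

- **Sidedness.** The default exceedance rule is |KS_t| ≥ |KS_0|, a
  genuinely two-sided test. A `literal-one-sided` mode counting
  KS_t ≥ KS_0 is provided; it is near-saturated (p ≈ 1) for strongly
  negative observed scores, which is why it is not the default.
- **No pseudocount** by default, so p = 0 is representable;
  `add_pseudocount=True` gives (f + 1)/(T + 1) for users who need
  strictly positive p-values.
- **Reproducibility.** Each drug's trials come from a dedicated
  substream seeded by (seed, SHA-256 of the drug id), so a drug's
  p-value does not depend on the order drugs are processed in or on
  any parallel scheduling.
- **Exact option.** When C(N, M) ≤ 10⁵ the exhaustive exceedance
  fraction over all subsets is available (`exact_when_feasible`); it
  doubles as the convergence oracle for the Monte-Carlo estimator in
  the tests.
- A comparison slack of 10⁻¹² absorbs the float division by M·N when
  comparing trial scores against the observed score.

## Query expansion

Direct queries are uppercased, trimmed, deduplicated, and split into
matched/unmatched against the reference kinase universe; unmatched
tokens are reported, never silently discarded, and an all-unmatched
query is an error. Family queries expand a kinase-family annotation
(the human kinome is conventionally divided into a handful of groups by
catalytic-domain sequence, but any user taxonomy works); GO queries
expand a biological-process term by exact id or by a name substring
that must resolve uniquely. Both annotation maps are plain TSV inputs;
there is no live ontology access and no GO-graph propagation — a term's
kinase set is exactly its listed kinases. No alias/HGNC resolution is
performed: symbols are compared verbatim after normalization.

## Synthetic data generator

The generator emulates a kinase selectivity panel without reproducing
any published dataset's marginals. Background K<sub>d</sub> values are
log-normal (location 0, scale 1 on log₁₀ μM by default — panels of
mostly-weak binders spanning a few decades around 1 μM, which is what
published selectivity screens look like in order of magnitude);
percent-inhibition backgrounds are 100·Beta(2, 5), i.e. mostly modest
inhibition with a light right tail. Spiked drugs have their target
kinases set at least a configurable potency-gap factor (default 100×)
better than their own best background value, which guarantees the
targets occupy the top ranks by construction.

What the generator does *not* emulate: correlated off-target structure
between chemically similar drugs, family-driven cross-reactivity,
assay noise or censoring at panel detection limits, and the exact
marginal distributions of real panels. Passing the recovery tests
therefore demonstrates the scoring engine's correctness and power under
clean spiked signal, not its behavior on the correlation structure of
real selectivity data.

Default study conditions used by the tests and the acceptance script:
recovery runs use 15 drugs × 60 kinases with a 3-kinase target set at
gap 100×, T = 500 permutations, 100 seeds; the database-shape run uses
72 drugs × 442 kinases (the size of the larger published
K<sub>d</sub>-type panel) with four engineered single-target-specific
drugs. With a single-kinase query against a 442-kinase profile whose
target sits at rank 1, only ranks 1 and 442 are as extreme under the
two-sided null, so the permutation p-value concentrates near
2/442 ≈ 0.005 — small single-kinase queries can be strongly
significant despite M = 1.

## Package shape

The scoring pipeline is exposed three ways over one implementation:
module-level functions mirroring the processing stages (load → rank →
query → connect → permute), a scikit-learn-style estimator
(`ConnectivityMapper`, fit on the reference then `connect`/`transform`
queries, composable with sklearn tooling via
`get_params`/`set_params`), and a CLI (`kinconn connect|rank|simulate`)
with atomic output writes, fixed print precision (4 decimals for
scores, 3 for p-values) for stable golden files, and a provenance
header recording version, seed, trial count, assay type and input
digests.

## Known limitations

- Scores compare drugs *within* one database; P and Q are per-query,
  per-database extremes, so normalized scores are not comparable
  across databases or across queries.
- No multiple-testing correction across drugs: p-values are raw
  per-drug permutation estimates.
- Kinase identity is the verbatim symbol string; mutant or phospho-
  variant entries are distinct only if their symbols differ.
- A drug whose profile contains few of the query kinases is scored on
  the reduced set (small effective M); `n_matched` is reported so such
  rows can be filtered, but no penalty is applied.
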