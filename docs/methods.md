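# Methods

## Signed-rank profile model

A reference profile is a signed permutation over the probe universe: the
multiset of rank magnitudes is exactly {1..N}, the sign is the regulation
direction. The convention that the *most* differentially expressed probe
carries magnitude N (not 1) is deliberate: with it, the normalisation
constant c_max = Σᵢ₌₁..m (N − i + 1) is the largest value the raw strength
c = Σ s(gᵢ)R(gᵢ) can take, so the connection score C = c/c_max reaches ±1
exactly at the two extremal configurations and nowhere else.

`build_profile` ranks probes by descending |statistic|. Ties are broken by
universe order (the earlier probe takes the larger magnitude); the original
reference-database construction does not document its tie rule, so ours is
a declared convention chosen for run-to-run reproducibility, not an
inference. A zero statistic is given sign +1, since a signed rank must be
nonzero; this only matters for probes in the noise floor.

## Set score

A compound's setscore is the arithmetic mean of the per-replicate
connection scores. Because every replicate shares one c_max, this equals
the score computed on the per-probe *mean* signed-rank vector of the set —
an algebraic identity the scoring engine exploits (see *Null stream*
below). The mean is the simplest combination rule consistent with a K = 1
set reducing to the single-profile score; a variance-scaled mean is the
main alternative, and the `scores_from_ranks` helper (which scores directly
from a signature-probes × replicates signed-rank matrix, the form in which
published per-compound excerpts circulate) exposes the per-replicate scores
so either combination can be audited against published setscores when such
excerpts are available.

## Randomization null and significance

The null hypothesis for one reference set is "a signature of this length
carries no information about this compound". It is sampled by drawing
random signatures: m *distinct* probes uniform from the universe, with the
query's multiset of signs assigned in a fresh uniform order per draw.
Preserving the sign multiset (rather than flipping fair coins) keeps the
null conditional on the query's up/down composition, which matters for
strongly one-sided signatures.

The p-value is the add-one estimator (b + 1)/(n_random + 1) on the
two-sided event |C_random| ≥ |C_observed|. It can never return 0, so
Bonferroni scaling stays meaningful at any n_random; the cost is a
conservative bias of order 1/n_random. A tolerance of 1e-12 on the ≥
comparison keeps exact ties (common in tiny enumerable universes) counted
as extreme.

One null stream is drawn per (query length, database) — seeded by
(seed, m) — and shared across all D sets of that query, mirroring a single
randomization benchmark per signature size and cutting the cost D-fold.
Sharing induces a mild positive correlation between the D p-values of one
query; their *marginal* distribution remains uniform (verified by the
calibration test), and the Bonferroni guarantee, which needs only the
marginal level, is unaffected. Scoring a random signature against a set
costs O(m) via the mean-rank identity, so one query is
O(n_random · m · D) gather-multiply operations; the default test-scale
setting (n_random = 2×10⁴, D = 200, m = 10) runs in well under a second.

The config invariant n_random ≥ 10·D/α ensures at least ~10 resolvable
p-value steps below the Bonferroni threshold α/D. The dataclass default is
n_random = 10⁶, sized for databases of >1,000 compounds; the tests and the
acceptance script pass 2×10⁴–10⁵, which satisfies the invariant with
margin at their D.

## Family-wise control and the FDR estimate

Each of the D compound sets is tested at α/D with family budget α = 1 by
default, i.e. at most one expected false positive per query. The achieved
FDR after selection is then estimated as α/n_sig. This estimator is the
unique reading under which published full-database runs with 271 and 154
significant compounds both meet an FDR target of 0.01 (1/271 ≈ 0.0037,
1/154 ≈ 0.0065), and it makes the optimal-size search concrete: the
smallest m on the grid (default 5, 10, …, 100; the original study does not
print its grid) with ≥ 1 significant hit and α/n_sig ≤ target. Note the
structural consequence: with α = 1 a target of 0.01 needs ≥ 100
significant compounds, so desk-scale synthetic tests of the size search
use proportionally larger targets rather than pretending a 200-compound
toy database can yield 100 hits.

The Bonferroni divisor is the number of compound *sets* (D), not of
individual treatment instances, since results are reported per compound.
Significance is two-sided (on |C|): a single query surfaces both
phenotype-enhancing (C > 0) and phenotype-suppressing (C < 0) candidates,
with the sign reported alongside.

## Perturbation stability

Each of the m leave-one-out variants of the query (omit entry i, restore
it before omission i+1) is re-queried at its own length's threshold with a
fresh null stream for length m−1, seeded by (seed + 1 + i, m−1). The
stability of a base-significant compound is the fraction of the m variants
under which it stays significant; only base-significant compounds are
scored. "Omission with replacement" is read as restore-then-omit-next, not
substitution by the next-ranked gene; substitution is a conceivable
alternative reading and the config carries a `perturb_mode` field so it
could be added without an interface break, but omission is the default and
only implemented mode.

## Signature construction

The DE table's `position` column is the ranking authority — it preserves
the source tool's own tie-handling (ascending p, sub-sorted by
|log2ratio| at equal p) — and the builder never re-sorts by p. The walk
appends, per gene in position order, all annotated probes (in annotation
order) present on the platform, each carrying the gene-level sign of
log2ratio; unmapped genes are skipped, and collection cuts exactly at m,
possibly mid-gene. This cut-at-m behaviour is observable in the bundled
example: the ten-probe signature covers seven genes, with a three-probe
gene contributing its full block.

## Cross-platform comparison

The overlap population is the compounds that are significant *and* fully
stable on each platform. The tail P(X ≥ k) with
X ~ Hypergeometric(D, n_A, n_B) is computed exactly (scipy's `hypergeom.sf`,
validated in tests against a rational-arithmetic sum to 12 significant
digits and a brute-force oracle on small populations); the ≥ convention is
stated to prevent off-by-one drift. Sign concordance is the fraction of
shared compounds whose setscores agree in direction; a zero setscore is an
error (no direction), an empty overlap returns NaN.

## Synthetic data

The generator emulates the study conditions: a probe universe standing in
for a microarray platform, D compound sets with replicate counts uniform
over K_range, a ranked DE table with a strongly significant top tier
(|log2ratio| lognormal around 3, p-values spread over 10⁻³⁰⁰–10⁻²⁰, 90%
up-regulated), and an annotation map in which a gene is unmapped with
probability 0.3 (three of the top ten genes in the motivating example),
maps to 2–3 probes with probability 0.2, else to one probe.

Null profiles are uniform signed permutations (magnitudes a uniform
permutation, signs independent fair coins). A planted compound's replicate
starts null, has the planted signature's probes swapped into magnitudes
N, N−1, … with matching signs (direction −1 flips them), then each planted
probe is independently swapped with a uniformly chosen probe with
probability 1 − λ. Swap-corruption rather than additive rank noise keeps
every profile an exact signed permutation at every strength — λ = 1 forces
C = ±1 exactly, λ = 0 is null up to O(m/N) edge effects — which is why
the permutation invariant can be asserted unconditionally on generated
data. `gen_pipeline_inputs` ties the pieces together: the planted
signature is defined as the top-m mappable probes of the generated DE
table, so signature construction genuinely recovers it.

What the generator does *not* emulate: correlated probes within a gene,
compound-class structure among nulls (real profiles of related drugs
correlate), dose/cell-line stratification, and heavy-tailed DE statistics.
Passing tests therefore demonstrate correctness of the scoring and
inference machinery under the stated null and planted alternatives, not
performance on real reference collections.

## Problem sizes and defaults

Desk-scale defaults (N = 2,000, D = 200, K ≤ 8) keep a full pipeline run
— simulate, build, query, perturb, rank — under half a minute;
`SyntheticConfig.paper_scale()` switches to the platform-scale universe
(N = 22,283, the HG-U133A probeset count, which is also the default N for
scoring published signed-rank excerpts) with D = 1,309 and setsizes up to
32. The calibration check uses N = 1,000, D = 200, K = 2 over 50 seeds;
the recovery check uses λ = 0.9, m = 10, D = 200, K = 4 over 20 seeds.
The acceptance script runs the same two at 20 and 10 seeds respectively.

## Numerical choices and degenerate inputs

- Tie-breaks: universe order in profile building; compound name as the
  final ranking key.
- m ≥ N makes the randomization null degenerate and is rejected, as are
  empty signatures, empty sets and empty databases.
- Signatures may not contain duplicate probes; a probe annotated to two
  genes enters a signature once, under the earlier-ranked gene.
- p-values of a query are reproducible bit-for-bit given (seed, m,
  n_random); file round-trips of databases, signatures and DE tables are
  bit-exact (tab-delimited, header row, UTF-8).

## Known limitations

- The randomization p-value floor is 1/(n_random + 1); queries against
  very large D need n_random raised accordingly (the config invariant
  enforces the minimum, not a comfortable margin).
- The set-level null re-scores random signatures against the *actual*
  replicate mean-rank vector, so replicate correlation within a set is
  respected, but correlations *between* different compounds' sets are not
  modelled in the null.
- Stability is defined only at the base query's α and D; it is monotone
  non-increasing as the threshold tightens, but the implementation does
  not expose threshold sweeps.
- The published per-compound signed-rank excerpts that would pin down the
  set-score combination rule against printed setscores are external
  supplementary downloads; the bundled data cover the signature
  construction and cross-platform comparison examples only.
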