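# Methods

## Edge scores and their transfer

Template networks weight each undirected edge with a log likelihood
score (LLS): the natural log of the likelihood of functional association
between the linked proteins relative to chance. The score is additive
in log space, which is what makes orthology adjustment a sum: for a
template edge (A, B) and orthologous query proteins A′, B′ with
inparalog scores s₁ = s(A–A′) and s₂ = s(B–B′),

    LLS(A′–B′) = LLS(A–B) + ln s₁ + ln s₂.

Because s ∈ (0, 1], the adjustment can only lower the score; two perfect
orthologs (s₁ = s₂ = 1) transfer the template score unchanged.
`likelihood_ratio` exposes the inverse mapping exp(LLS) (LLS 4 ≈ 55-fold
over chance; LLS 0 = chance).

Filtering is strict on "below chance": candidates with adjusted
LLS < 0 are dropped, a score of exactly 0 is retained. When co-ortholog
fan-out makes several template edges land on the same unordered query
pair, the default aggregation keeps the **maximum** adjusted score and
its provenance. Transferred scores that share a template are not
independent evidence, so summing would overcount; a `sum` mode exists
behind a config switch for sensitivity analyses. Self-loops (both
template endpoints mapping to one query protein) are dropped: functional
association networks are defined over distinct proteins.

## Ortholog mapping

The mapping follows the published two-way-best-hit + inparalog-confidence
scheme. Over all-vs-all pairwise similarities:

* a pair (A, A′) **seeds** a group iff each protein is the other's
  highest-scoring cross-species hit; seeds score s = 1;
* a same-species paralog P of A with sim(P, A) ≥ sim(A, A′) joins the
  group as a co-ortholog of A′ with
  s = (sim(P, A) − sim(A, A′)) / (sim(A, A) − sim(A, A′)),
  clamped to (0, 1] (the degenerate denominator sim(A, A) = sim(A, A′)
  assigns s = 1, logged); the query side is symmetric.

Determinism rules, chosen so identical inputs give identical outputs
regardless of ordering: best-hit ties go to the lexicographically
smallest partner id; a protein qualifying for several groups joins the
one whose seed member it resembles most (ties to the smallest group id);
seed members never join other groups as inparalogs.

The default similarity is a full Smith–Waterman local alignment with
BLOSUM62 and affine gaps (open 11, extend 1 per residue), converted to
bits with the Karlin–Altschul transform using the published gapped
constants for this matrix/penalty combination (λ = 0.267, K = 0.041).
Hits are kept when they reach **40 bits** and the alignment covers at
least **50%** of the longer sequence — the published defaults of the
InParanoid tool — and both cutoffs are configurable. The scorer is
pluggable, and precomputed ortholog tables (five-column TSV) bypass the
internal mapping entirely, so genuine INPARANOID output is drop-in after
reformatting. Full pairwise alignment is quadratic in proteome size;
it is intended for desk-scale proteomes and for validating the planted
fixtures — for genome-scale runs, supply a precomputed table.

## Annotation subnetworks

Query proteins inherit the union of GO/KEGG terms annotated to any
template member of their co-ortholog group (a seed-only mode is
available); the inheriting template proteins are recorded as provenance.
Terms are used as flat sets — no propagation up the GO hierarchy. A
term's subnetwork is the induced subgraph over its annotated query
proteins with edges at or above an adjustable LLS threshold; annotated
proteins with no qualifying edge remain listed with connectivity 0.
Hub ranking scores each node by the sum of its within-term edge LLS
(descending, lexicographic tiebreak), which satisfies the handshake
identity Σ node scores = 2 Σ edge scores — asserted in the tests.

## Benchmark

The gold standard is derived from pathway-style gene sets over query
proteins: positives are unordered pairs sharing ≥ 1 term, negatives are
pairs of annotated proteins sharing none. Pairs touching unannotated
proteins are not classifiable and are excluded from the precision
denominator — standard practice for incomplete gold standards.

*Precision–coverage*: links sorted by adjusted LLS descending are walked
in bins (default 1000 links; smaller for desk-scale fixtures); after
each bin the cumulative precision over evaluable links is paired with
the coding-genome coverage (distinct nodes seen / proteome size). The
curve is cumulative by default; a per-bin mode is available.

*Per-pathway AUC*: each universe protein gets a guilt-by-association
score — the sum of adjusted LLS over its edges to pathway members,
excluding itself (which is automatic, as the network has no self-loops
and membership of the protein itself contributes no edge). The AUC of
members vs non-members comes from the Mann–Whitney rank formula with
ties contributing 0.5; it equals the exhaustive fraction of correctly
ordered (member, non-member) pairs, which the tests verify by brute
force. Only pathways with ≥ 5 members present in the universe are
scored. Distributions are summarized as box-plot statistics with
linear-interpolation (type-7) quantiles and 1.5·IQR whiskers.

**Finite-universe calibration bias.** Under the null (random scores,
random labels) a member can connect to at most m − 1 other members while
a non-member sees all m, so member scores are slightly depressed and the
mean null AUC sits just below 0.5 — about 0.47–0.48 for pathways of
5–20 members over a 200-protein universe (500 simulated pathways). The
effect shrinks as universe size grows relative to pathway size and is
negligible at genome scale. We keep the plain sum statistic rather than
normalizing it away, because it is the statistic the benchmark is
defined on; the calibration test bands (0.45–0.55) account for it.

## Synthetic fixtures

The generator plants: disjoint pathway cliques in the template network
with edge LLS ~ Normal(3.0, 0.5) clipped below at 0.5 (typical of
confident functional-network edges), background edges at rate 0.01 with
LLS ~ Uniform(0.2, 1.2); a one-to-one orthology (configurable to
arbitrary planted maps and scores); and protein sequences of length 90
where each query ortholog is a point-substituted copy of its template
counterpart (5% per-site divergence, plus 0.35·(1 − s) for planted
scores below 1 — a calibration constant chosen so the default aligner
recovers the planted structure, not a claim about real evolution). A
ground-truth ledger records every expected transferred edge and score by
direct enumeration that is independent of the pipeline code.

What the fixtures do **not** emulate: realistic phylogeny (no indels, no
rate heterogeneity, no gene birth/death), overlapping pathway
membership, annotation noise, or the incompleteness of real gold
standards. Passing tests therefore demonstrate the contracts of the
computation — transfer arithmetic, filtering, ranking, benchmark
statistics — not performance on real proteomes.

All fixture randomness flows from a single integer seed through one
`numpy` generator; identical specs are byte-identical on disk.

## Problem sizes

The test suite and acceptance script run at desk scale: 60–250 protein
proteomes, networks up to ~5 300 edges for the identity-transfer check,
500 simulated pathways over a 200-protein universe for the null
calibration, and ≤ 12-protein proteomes wherever full pairwise alignment
is exercised. These sizes make every check exact or statistically stable
while keeping a full run in seconds.

## Known limitations

* One template at a time: no Bayesian integration of several templates
  into a single network.
* No identifier cross-referencing; protein ids are used verbatim and
  case-sensitively.
* The internal aligner is for small proteomes; genome-scale ortholog
  mapping should come from a dedicated search tool via the table path.
* Serialized networks store the adjusted and template LLS but not the
  individual inparalog score pair; reading a network back reconstructs
  only their product.
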