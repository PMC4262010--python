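# Methods

## Scope and model

`quantweb` analyses quantitative bipartite antagonistic webs: a matrix
`a[i, j] ≥ 0` of interaction events between host species i (rows) and
parasitoid species j (columns), grouped into studies. Matrix size
`m = Σ a_ij` — the number of individual parasitism events — is the
package's central covariate, because the Shannon-based structural
metrics are strongly size-dependent and cross-study comparisons that
ignore this conflate sampling effort with biology.

Hosts recorded but never parasitised are legitimate members (all-zero
rows, "empty web" handling) and count towards the species total S used
by weighted connectance. All-zero parasitoid columns are rejected on
ingest: rearing-based sampling is host-focused, so a parasitoid can
only be observed through at least one interaction. Latitude is stored
signed; models use its absolute value (the hypotheses are
equator-to-pole, hemispheres pooled).

## Metrics

Entropies are computed in nats with `0·ln 0 = 0`; effective numbers via
`exp` are identical to the base-2 formulation because the base cancels.
Generality, vulnerability, linkage density and weighted connectance are
as defined in the README. Two identities hold to machine precision and
are asserted as tests: `LD = (G + V)/2` and `Cw = LD/S`.

**H2′ entropy bounds.** H2′ rescales the observed interaction entropy
between the extremes attainable by non-negative *integer* matrices
sharing the observed marginal totals; it therefore requires integer
count data (non-integer webs report NaN). After dropping zero
marginals, problems with ≤ 12 cells and ≤ 14 events are solved exactly
by depth-first enumeration. Larger problems use heuristics:

- minimum entropy (most concentrated): best of two greedy packings —
  repeatedly placing `min(remaining row, remaining column)` into the
  cell at the currently largest totals, and a variant that first
  consumes exactly matching row/column remainders (one placement can
  then empty both). Ties break to the lowest row then column index for
  determinism.
- maximum entropy (closest to independence): largest-remainder
  apportionment of `a_i. a_.j / m` under marginal caps, swept in
  descending remainder order with a small penalty on already-filled
  cells, followed (on webs of ≤ 100 cells) by 2×2 exchange moves that
  preserve marginals while entropy increases.

Against an exhaustive-enumeration oracle over every integer matrix with
m ≤ 10 and dimensions ≤ 3×3, the package's H2′ is exact (the exact
path covers that regime); the heuristics are additionally required in
tests to bracket the observed entropy and to track the oracle within
0.02 on spot-checked larger marginals. Degenerate marginals
(`H2_max = H2_min`, no specialisation freedom) report H2′ = 0 for a
single network — "no deviation from expectation" — but are treated as
*unmeasurable* during replicate averaging (below).

Exact integer-scale invariance of H2′ (multiplying all cells by k)
does **not** hold on small sparse webs — enumeration shows the
attainable extremes shift with granularity — so approximate scale
invariance is asserted only on dense matrices.

**Modularity.** Weighted bipartite modularity
`Q = (1/m) Σ (a_ij − a_i. a_.j/m)·1[same module]` over mixed
host–parasitoid modules. Q of the single-module partition is exactly
0, and zero-marginal hosts contribute nothing wherever placed. The
optimiser is simulated annealing over single-node reassignments (O(1)
move deltas from cached per-node module sums) with occasional module
merges: initial temperature calibrated so typical uphill-sized moves
accept ~50 % of the time, geometric cooling at 0.995 per move, stop
after 2000 moves without improvement, several independent chains, and
a greedy single-node polish. Per-chain seeds derive from the master
seed through a counter scheme, so results are reproducible from
configuration. On every small-web test case (≤ 8 nodes) the annealer
reaches ≥ 0.99× the exhaustive optimum across 5 seeds; in practice it
attains it exactly.

**Taxonomic diversity Δ.** Pairwise distances count equal-length rank
steps to the lowest shared rank (conspecifics 0, congeners 1, …, an
implicit root above the top rank) and are linearly rescaled so the
largest realised distance in the classification is 100 — the
convention of the standard community-ecology implementation, verified
against it on the worked examples. Distances are scaled on the *whole*
classification, then subset per network, keeping Δ comparable across
networks. Δ weights host pairs by abundance `x_i` (host marginal
totals by default; presence mode `x_i = 1` is provided because
compilations rarely state the choice) and divides by `N(N−1)/2`.

## Rarefaction

An integer web is a multiset of m events; a subsample of n is a
multivariate hypergeometric draw on the cells (without replacement),
which makes the full-size draw reproduce the original network
bit-exactly. Species membership of a subsample follows the same rule
as the original data: a species enters through its sampled events.
Hosts that were all-zero rows in the original web are study-design
records and are carried into every subsample; hosts and parasitoids
whose events are all sampled out are dropped. The shrinking species
count S is what drives weighted connectance downward at small sizes —
keeping the full roster instead would force connectance *upward* with
size, contradicting the canonical subsampling pattern.

Curves default to a geometric grid of ≤ 25 sizes from 2 to m, with 100
replicates per size (50 for modularity, which costs an optimiser run
per replicate). Replicate seeds derive from (master seed, network,
size, replicate) so parallel or partial runs are reproducible.

H2′ replicates whose subsampled marginals are degenerate are excluded
from the replicate mean: every 2-event draw is degenerate, and
averaging such draws in as "0 = perfectly unspecialised" manufactures
a spurious positive size trend in mean H2′ of roughly 0.1 per log
unit, destroying the index's designed scale independence. Sizes where
every draw is degenerate report NaN (the full-size draw keeps the
network-level 0 convention so the endpoint identity holds).

Standardisation subsamples every eligible integer network to a common
size (default 65 events — chosen as a typical second tercile of
compilation matrix sizes; `empirical_tercile` computes the
interpolated-inverse-CDF quantile of any given collection) and reports
replicate means together with the original m, for regressions of
standardised structure on original size. Networks smaller than the
standard size are excluded and listed.

## Mixed models

All five analysis stages share one toolkit built on Gaussian linear
mixed models (statsmodels MixedLM): study-level random intercepts,
optionally random slopes on log size, or a network-within-study
variance component for rarefaction tables. Model comparisons use
maximum likelihood; the final minimum adequate model is refitted with
REML for reporting. Likelihood-ratio tests of fixed effects refuse
REML fits. `AIC = −2ℓ + 2k` and `AICc = AIC + 2k(k+1)/(n−k−1)` count
k = fixed coefficients + covariance parameters + the residual
variance. Random-structure selection keeps the richer structure only
when it improves the criterion (AIC; AICc for the standardised-size
and residual stages, whose effective samples are small) by more than
1 — parsimony breaks ties. Backward elimination removes the
least-significant removable fixed term (interactions before their main
effects — marginality is never violated) while its LRT p ≥ 0.05, and
logs the full removal path. Non-convergence and boundary/singular
covariance estimates are flagged on the returned fit, never silently
dropped; a candidate whose fit fails is kept with a warning.

Stage recipes (response transforms): sizes stage — log all metrics
except H2′; subsampled and standardised stages — log except H2′ and
modularity; Δ stage — log except H2′ and connectance (Δ gets a random
slope for generality); residual stage — untransformed residuals
against guild + |latitude| + Δ + all two-way interactions with a study
random intercept. Values that are non-positive under a log recipe are
dropped with a warning.

**Residual type.** The residuals fed to the latitude/guild stage are
*marginal* (observed minus fixed-effects prediction). Conditional
residuals — subtracting predicted study effects — would absorb any
between-study signal, and latitude is constant within a study, so the
latitude test would have essentially no power by construction; with
marginal residuals the refitted study intercept keeps the test's
type-I error at its nominal level (measured ≈ 0.04 at α = 0.05 over
200 null simulations) while an injected 0.005-per-degree shift on H2′
residuals is detected with power ≈ 1. Conditional residuals remain
available via `resid_type`.

At this desk scale (tens of studies), LRTs of 4-df factor terms are
mildly anticonservative (~0.12 at nominal 0.05) — a known small-sample
property of the asymptotic χ² reference that full-data analyses share;
the calibrated, single-df latitude contrast is what the acceptance
checks quantify.

## Synthetic data generator

The generator emulates a literature compilation: 28 studies by
default, 1–15 networks each, matrix sizes log-uniform over 10–10⁴
(three orders of magnitude), latitudes uniform on −35…75 decimal
degrees, five host guilds, and a nested random taxonomy (branching
factors per rank; a final species-level factor allows conspecific
hosts). Host availability is lognormal (σ = 1, heavier 1.5 for the
species-rich rarefaction suites); each parasitoid draws a preference
vector from a Dirichlet whose *total* concentration is `10·θ` spread
over the host pool, so θ controls niche breadth independently of host
richness — θ → 0 gives single-host specialists (H2′ → 1), θ → ∞
uniform generalists (H2′ → 0), and median H2′ decreases monotonically
in θ. Cells are `m` multinomial draws, so matrix size is exact (a
requirement of the rarefaction contracts). Host and parasitoid
richness is partially coupled to m (coupling weight 0.7) — studies
that record more events sample more species, the accumulation
behaviour real compilations show. An optional switch biases
preferences toward taxonomically clustered hosts for Δ-coupling
experiments; it is off by default so the null generator stays null.

Latitude and guild effects are *not* built into network mechanics:
they are injected post hoc on the metric scale
(`apply_injected_effects`), giving exact known truth for recovery
tests; every generated collection ships a ledger of its generating
parameters.

The qualitative subsampling suite (rising generality/vulnerability/
linkage density, falling connectance, flat H2′) uses species-rich webs
— 200 potential hosts, 100 parasitoids, 1000 events, abundance σ = 1.5,
interaction-record-only rosters — the regime of the large rearing
studies in which that pattern is described: species accumulation must
continue across the whole size range, otherwise linkage-density growth
overtakes S and the connectance trend becomes U-shaped. Smaller or
more even webs genuinely do not show a monotone connectance decline.

What the generator does **not** emulate: real host phylogenies (its
taxonomy is a random balanced-ish tree), temporal or spatial structure
within studies, parasitoid-side taxonomy, density-dependent parasitism
or any population dynamics, and non-integer (rate-based) webs.
Passing tests therefore demonstrate that the pipeline's statistical
machinery is correct and calibrated under its stated assumptions — not
that real compilations satisfy those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run on one CPU in minutes by choosing
representative problem sizes: 10–20 networks for the rarefaction
suites (100 replicates per size, 50 for modularity), a 60-network
collection for the standardisation null, 200 simulations for type-I
error, 50 for power, and exhaustive oracles confined to ≤ 10-node webs
(modularity) and ≤ 3×3, m ≤ 10 matrices (entropy bounds). Determinism:
every stochastic component takes a seed, and derived seeds come from
`numpy.random.SeedSequence` spawning, so identical configurations
reproduce identical outputs.

## Known limitations

- The H2′ entropy-bound heuristics are not guaranteed optimal outside
  the exactly-solved regime; the documented oracle tolerance applies
  to the small-matrix suite, and bounds are clipped to bracket the
  observed entropy.
- Simulated annealing offers no optimality guarantee for large webs;
  replicate-mean modularity uses single chains for cost, trading a
  little downward bias that is shared across the networks being
  compared.
- Degrees of freedom for LRTs count fixed parameters only; variance
  components on the boundary are flagged but not corrected for.
- Δ assumes a single consistent host classification per collection;
  conflicting synonymies must be resolved upstream.
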