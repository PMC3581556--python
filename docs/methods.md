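# Methods

This note records the models, conventions and numerical choices behind
`middomain`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where genuinely open design
choices were resolved.

## The null model

The domain is a finite set of grid cells on an `n_rows × n_cols`
lattice (row = latitudinal band), not necessarily rectangular.
Adjacency is rook (4-neighbor) by default; queen (8-neighbor) is
available by configuration. Rook is the conservative choice — it is the
slower-spreading neighborhood and the more common one for spreading-dye
models; nothing downstream assumes either.

A random range is grown by the **spreading dye**: a seed cell is drawn
uniformly from the domain; then, repeatedly, an occupied cell is chosen
uniformly, one of its in-domain neighbors is chosen uniformly, and the
neighbor joins the range if unoccupied, until the range reaches the
species' empirical size. This "sequential disperser" reading is the
simplest faithful one; a frontier variant (uniform accretion over the
unoccupied neighbors of the current range) is available and induces a
different range-shape distribution (more compact ranges), though both
conserve size and cohesion exactly. If a seed lands in a connected
component smaller than the target size — possible on fragmented masks —
the attempt is discarded and reseeded, up to `max_restarts` (default
100) before an error naming the species. Growth under an acceptance
field (below) additionally carries an attempt budget per seeding so a
practically unreachable target cannot stall the simulation.

One iteration places every species independently; species identities —
and with them all phylogenetic, guild and trait attributes — are
untouched. Iteration `i` of an ensemble uses an RNG substream derived
from `(seed, i)`, so ensembles are bit-reproducible and any single
iteration can be regenerated in isolation. The growth loop is compiled
(numba); a 120-species placement on an 800-cell domain takes a few
milliseconds.

## The ten metrics

Per cell, from its species list. Cells below the minimum assemblage
size for an index carry a missing value (NaN): every metric except
richness is missing for empty cells; PSV, PSC, hypervolume and mean NND
require 2 species; MST-SD requires 3 (a single MST edge has no sample
SD under the n−1 convention — our choice, flagged here because only the
one-species case is conventionally fixed).

* **Richness** — the species count.
* **Faith's PD** — branch-length sum of the minimal subtree connecting
  the assemblage, root-inclusive by default (the dominant convention,
  and the one that makes single-species PD well defined as the
  root-to-tip distance); a root-exclusive flag exists.
* **PSV / PSC** — from the phylogenetic correlation matrix `C`, where
  `c_ij` is the shared root-to-MRCA path length scaled by
  `sqrt(depth_i × depth_j)` (shared depth over depth for ultrametric
  trees; the square-root standardization means non-ultrametric trees
  are accepted without assuming clock-likeness). PSV is one minus the
  mean off-diagonal correlation; PSC is one minus the mean, over
  members, of each member's largest correlation with another member.
  Both are verified against R `picante` in the test suite.
* **Guild metrics** — counts over a fixed guild vocabulary (six diet
  guilds by default). Shannon uses the natural log. Camargo evenness
  `1 − Σ_{g<h} |p_g − p_h| / G` normalizes by the number of guilds
  *present*, making evenness independent of guild richness (an
  all-guilds flag provides the alternative normalization).
* **Morphospace metrics** — on the Euclidean geometry of the (already
  log-transformed) trait matrix, without further standardization or
  whitening: box hypervolume (product of per-trait ranges), sample SD
  of MST edge lengths, and mean nearest-neighbor distance. MST ties are
  broken deterministically by the fixed edge ordering; the edge-length
  multiset is unique whenever pairwise distances are distinct. The
  vectorized per-cell scorer uses a compiled Prim's algorithm,
  cross-checked in the tests against `scipy.sparse.csgraph` and against
  exhaustive spanning-tree enumeration for ≤ 6 points.

The per-cell metric table is deterministic and independent of cell
order; the ensemble scorer pre-aligns tree/guild/trait structures to
one species ordering and reproduces the scalar operations exactly
(asserted to 1e−12 in the tests). Spearman summaries between metrics
use pairwise-complete cells (≥ 3 per pair, average-rank ties) over
occupied cells only, since unoccupied cells are outside every analysis.

## The inferential procedure

Per iteration, observed values are regressed (OLS) on expected values
over cells where both are non-missing *in that iteration* — the only
rule that keeps every fit well defined when simulated cells fall below
an index's minimum assemblage size; the per-fit cell count is recorded
so attrition is auditable. Cells with zero observed richness are
excluded from all fits. A fit needs ≥ 3 complete cells and variance in
the expected values; degenerate iterations are dropped and counted.
Summaries report means plus 95% and 99% percentile intervals of r²,
intercept and slope.

The ellipse test fits the sample mean and covariance of the (intercept,
slope) cloud and compares the squared Mahalanobis distance of (0, 1)
with the χ²(2) 0.95 quantile, 5.9915 — the plug-in probability-contour
operationalization of "assuming a bivariate normal"; an F-based
small-sample variant is available.

**Exact degeneracy.** Because range sizes are conserved exactly, the
expected metric's mean over a fixed cell set is *identical* in every
iteration for richness; with the observed mean equally fixed, every
regression line passes through the same point and intercept = ȳ − slope·x̄
exactly. The cloud is a line (correlation −1), and (0, 1) lies on that
line whenever ȳ = x̄ (always true for richness). The test therefore
computes the Mahalanobis distance on the covariance's numerical rank
(eigenvalues above 1e−9 of the largest) with the χ² threshold at that
rank; a point displaced off the degenerate subspace beyond rounding is
outside outright. Full-rank behavior is unchanged.

**Calibration and its limits.** For clouds drawn from a bivariate
normal centered on (0, 1), the plug-in ellipse contains the point ≥ 93%
of the time (nominal 95%; the deficit is sample-estimation slack).
The *scientific* test is only approximately calibrated, however: the
expected gradient is itself noisy, so the regression slope attenuates
toward `V/(V+Ve)` where `V` is the spatial variance of the ensemble-mean
gradient and `Ve` the per-cell iteration variance. The test behaves as
intended only where the deterministic mid-domain signal dominates
(`V ≫ Ve`) — true for number-type metrics with large ranges, and
systematically false for equitability-type metrics (PSV, evenness,
MST-SD), whose weak spatial signal makes the procedure anticonservative
even on data generated by the null. This mirrors the empirical finding
that equitability metrics fit the null poorly, and is a caveat on
interpretation, not a defect of the implementation.

## Synthetic worlds

The generator emulates the statistical shape of a continental bat
fauna; its defaults are the package's study conditions.

* **Domain** — 40 × 20 cells (latitudinally elongated), optionally
  thinned to a random connected mask grown by the same spreading dye.
* **Range sizes** — lognormal, median 35% of the domain, log-SD 0.7,
  truncated to [1, |domain|]. Chosen so that peak cell richness is
  roughly two thirds of the species pool, as in widespread Neotropical
  faunas; this also places the null test in its valid regime
  (`V ≫ Ve`). A cap (`size_max_fraction`) exists for scenarios where
  near-domain-wide ranges would be incoherent.
* **Phylogeny** — pure-birth (Yule) tree, rate 1, ultrametric by
  construction, 120 tips by default.
* **Traits** — independent Brownian motions along the tree, 7 traits,
  rate 0.03 per unit depth around log-scale baselines typical of
  bat-like morphometrics (tip SD ≈ 0.3–0.4 on the log scale).
* **Guilds** — six diet guilds, either independent-uniform or
  clade-conserved (the tree cut into six monophyletic groups).
* **Structured alternative** — each species prefers a latitudinal row;
  during growth a candidate cell is accepted with probability
  `exp(−s · max(0, |row − preferred| − w))`. The tolerance half-width
  `w` scales with the rows a range of that size minimally needs, and
  the preferred row is clamped so the band fits the domain: widespread
  species get broader tolerances, and size conservation remains
  feasible at any strength `s` (a pure exponential with `w = 0` is
  available and appropriate only for ranges small against the
  latitudinal extent). Preferred rows can be supplied externally; the
  phylogenetically structured variant rank-maps a Brownian latent
  variable to rows, so whole clades share latitudes. Strength 0 reduces
  exactly to the null model.

What the generator does **not** emulate: coastline geometry, empirical
range-size distributions beyond skewness, range-shape realism,
correlated trait evolution, or uneven guild frequencies. Passing tests
demonstrate internal correctness and the qualitative behavior of the
test under known truth — not that any particular empirical system is or
is not governed by mid-domain geometry.

## Problem sizes used in validation

The simulation studies run at: null self-consistency — 40 × 20 domain,
120 (and 30) species, 200 iterations, 30 replicates; power against
latitudinal structure — same domain, 120 species, sizes capped at half
the domain, niche strength 2 per row, 100 iterations, 30 replicates
(null and structured observations share each replicate's world and
ensemble, so the comparison is paired); the complete pipeline run uses
50 iterations. These sizes give stable verdict frequencies while
keeping each study in the minutes range on one CPU.

## Known limitations

* The regression-ellipse procedure is anticonservative for low-signal
  metrics (above); verdict differences between metrics partly reflect
  signal strength, not only mechanism.
* `functional_richness` saturates (all guilds present everywhere) in
  rich simulated worlds, leaving no expected gradient; such fits are
  reported as degenerate rather than forced.
* Polytomies are accepted as-is; no branch-length re-estimation or
  tree manipulation is performed.
* The latitudinal-band domain rule (cells between the outermost
  occupied rows) is the default reading of "domain bounded by the
  fauna's latitudinal limits"; an exact-footprint rule is available by
  configuration.
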