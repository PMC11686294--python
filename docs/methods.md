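# Methods

This note documents the models, numerical conventions, and design choices
behind `tfbscape`, and what the synthetic-data generator does and does not
emulate.

## Genotype space

A `GenotypeSpace` is a string length L over {A,C,G,T} plus an optional
fixed context.  The default is the 8-position TetR operator library:
variable positions embedded in `TCCCNNNNAGTNNNNGAGA` (wild type
`TATCGATA`, i.e. the *tetO2* sequence `TCCCTATCAGTGATAGAGA`).  Genotypes
are handled everywhere as the L variable characters; Hamming arithmetic
and network adjacency are defined on those characters only.  The complete
space is a Hamming graph with 4^L nodes and 3L neighbors per node.

## Ground-truth landscape generators

* **Additive**: score(g) = Σₚ w_p(g_p) from per-position, per-allele
  weights.  With distinct weights the landscape has exactly one local
  maximum and every shortest path to it is strictly uphill — the smooth
  control.
* **NK** (circular neighborhoods): score = mean over L component
  functions, each an i.i.d. uniform table over the site and its K
  right-hand neighbors.  K = 0 reduces to additive (up to a constant);
  K = L−1 matches House-of-Cards statistics.  K tunes ruggedness.
* **House-of-Cards**: i.i.d. scores (uniform by default).  On the complete
  4-allele graph the expected number of local maxima is 4^L/(3L+1) — each
  genotype is a peak iff it is the largest of its (3L+1)-element closed
  neighborhood — used as the analytic ruggedness benchmark.

All generators are deterministic given their seed (numpy `default_rng`).

## Sort-seq forward model

The simulator emulates the structure of the sorting assay, not instrument
physics:

* **Repression → fluorescence**: F(r) = max(f_auto, f_max · 2^(−slope·r)),
  a log-linear decreasing map saturating at the autofluorescence floor of
  a promoterless control.  Defaults f_max = 8192, f_auto = 64,
  slope = 5.6 log₂-units per repression unit place r ∈ [0, 1.25] across
  the full dynamic range, with the strongest repressors at the floor.
  No functional form is dictated by the assay itself; log-linearity
  matches the log-scale binning and the observed near-linear relation
  between log fluorescence and repression scores.
* **Gates**: 13 bins.  The upper bound of bin 1 is the median
  autofluorescence of the control; the lower bound of bin 13 is the 95th
  percentile of a pre-sort recording of the simulated library; interior
  boundaries are equidistant in log₂.  This mirrors the sorting protocol
  structurally rather than using arbitrary quantiles.
* **Noise**: each cell draws log-normal noise (sd 0.35, natural log)
  around F(r); each (genotype, replicate) additionally draws one
  multiplicative log-normal factor (sd 0.30).  The replicate factor was
  calibrated once so that per-replicate repression scores correlate at
  R ≈ 0.86–0.90 across replicates — the band reported for the real
  assay — and then frozen.
* **Reads**: per replicate, reads are drawn from one multinomial over the
  flattened genotype × bin cell-occupancy matrix, so counts sum exactly
  to `reads_total` (default 100 per genotype, putting median depth near
  100 so the ≥30-read filter trims only the lower tail).
* **Dropout** (post-sort diversity loss) is available via
  `dropout_fraction` but defaults to 0: the quality filters already
  exercise the missing-genotype code path, and dropout rates in real
  experiments are protocol-specific.

Not emulated: raw reads, barcodes/adapters, PCR bias, sorter impurity,
cell-cycle or plasmid-copy-number effects.  Consequently, passing
recovery tests shows the scoring pipeline inverts *this* generative
model; it does not validate the assay itself against those artifacts.

## Scoring

e = Σ xᵢwᵢ/Σ xᵢ with wᵢ = 1…13 (e ∈ [1, 13]); r = 14 − e; S = r / r(wild
type), so S(wild type) = 1 exactly and observed scores span ≈ 0–1.25.
Filters, in order: presence (> 0 reads) in every replicate; ≥ `min_reads`
total reads per replicate (a per-bin variant is available behind
`per_bin_threshold`, but requiring 30 reads in *every* bin would discard
nearly everything and is not the default); replicate CV of r ≤ 0.5.  The
CV uses the sample s.d. (ddof = 1) of pre-normalization r — normalizing
by a common constant leaves CV unchanged.  τ is the s.d. of the
wild-type-normalized per-replicate scores, the scale on which the noise
model compares neighbors.  The funnel (count surviving each filter) is
recorded in the table's attrs and in the pipeline manifest for audit.

## Landscape construction

Adjacency is the Hamming-1 relation restricted to observed genotypes,
built vectorized via base-4 integer encoding for spaces up to 4^12.  The
largest connected component ("giant component") is extracted before
analysis; ties between equal-sized components break deterministically to
the component containing the lexicographically smallest genotype.

Edges are oriented uphill (low S → high S) everywhere.  Score equality is
exact floating-point equality by default; an `epsilon` tolerance can
widen plateau membership.  Exact ties yield no directed edge and define
plateau links.

**Noise model.**  With per-node τ (optionally inflated by a common scale
factor), A is *distinguishably higher* than neighbor B iff
S_A > S_B + τ_B and S_A − τ_A > S_B + τ_B.  A distinguishable pair gets
one uphill edge; an indistinguishable pair gets edges both ways (walks
and accessibility may traverse them as non-decreasing steps).  With τ ≡ 0
the noise-free landscape is reproduced exactly: an exact tie between two
zero-τ nodes stays undirected rather than becoming bidirectional.

**Peaks.**  Two counts are maintained because they trend oppositely with
noise:

* *local maxima* (no distinguishably higher neighbor) — the plateau
  members and walk-absorbing states; this set can only grow as τ grows;
* *strict peaks* (every neighbor distinguishably lower) — the count that
  measurement noise smooths away; this set can only shrink as τ grows.

Without noise (and without ties) the two coincide.  Plateaus are
connected components of local maxima joined by indistinguishable links;
peak breadth is local maxima per plateau.  The noise sweep reports both
counts, plateau count, breadth, and the walk outcomes at each scale, with
fixed starts and seeds so differences reflect the noise model alone.

**Shuffled nulls** permute the score multiset uniformly over the fixed
node set and recount peaks with the noise-free definition, giving the
uncorrelated-landscape benchmark for the observed peak count.

## Topography

* **Basins**: reverse reachability from the peak over permitted steps;
  members exclude all peak-labeled nodes, and fractions use one
  consistent denominator (non-peak genotypes in the landscape).
* **Paths**: shortest accessible path length is BFS on the directed
  graph.  The shortest-path census counts *minimum-length* undirected
  paths and the accessible subset by dynamic programming over the
  shortest-path DAG — exact, because accessibility is a per-edge
  property — rather than listing paths explicitly.  All-length
  accessibility questions are answered by reachability (basins); explicit
  all-length enumeration grows combinatorially and adds no information
  about which peaks are accessible.
* **Epistasis**: every square {g, gA, gB, gAB} with all four corners
  observed is enumerated once (canonically from the corner with the
  alphabetically smallest alleles at the two varying positions) and
  oriented with the top-scoring corner as the double mutant.  Reciprocal
  sign: both singles below the background, double above it.  Simple sign:
  exactly one single below both background and double, the other
  intermediate (evaluated in both orderings).  Additivity and magnitude
  epistasis pool into "no sign"; boundary ties resolve to no-sign.
  Squares with missing corners are skipped.
* **Distances**: Hamming distances over all distinct unordered pairs;
  on the complete space the mean is (3L/4)·n/(n−1) (self-pairs excluded).
* **PCA**: one-hot 4L design matrix, scikit-learn PCA.  In a
  combinatorially diverse library each component explains little
  variance; this is expected, not a defect.

## Adaptive walks

* **Greedy**: step to the strictly best uphill neighbor; deterministic.
  Equal-gain ties break lexicographically by default (a random tie-break
  is available) so that repeated runs are identical.
* **Uniform (SSWM)**: uniform choice among strictly uphill neighbors;
  terminates at a local maximum because the strict uphill relation is
  acyclic.  An exact endpoint distribution (probability-mass propagation
  in increasing-score order) complements the Monte-Carlo engine; its
  support equals basin reachability by construction, which the tests
  verify against the independent reverse-BFS oracle.
* **Kimura**: per proposal step, one neighbor of the currently fixed
  genotype is drawn (uniformly, or weighted by a user-supplied 4×4
  relative mutation-rate matrix; the default is uniform since no
  canonical rate table is bundled) and fixes with probability
  f = (1−e^(−2s))/(1−e^(−2Ns)).  Proposals that fail still consume one of
  the `max_steps` (default 1000) iterations, and every peak occupied en
  route is recorded, so a single walk can visit several peaks.
  Numerics: s → 0 returns 1/N; −2Ns > 700 switches to log space, so
  strongly deleterious mutations underflow cleanly to probability 0; for
  s > 0, f ≥ 1 − e^(−2s) with equality in the N → ∞ limit.
* **Starts**: all non-peak genotypes, a seeded random sample, or an
  explicit list; per-start walk counts are configurable.  The high-peak
  threshold is S > 1 (above wild type) unless overridden.

Polymorphic populations (Wright–Fisher/Moran, standing variation) are out
of scope; clonal interference is represented only by the greedy proxy.

## Problem sizes

Tests and the acceptance script run at desk scale: complete spaces up to
4^5 for brute-force oracles, 4^8 for the combinatorial censuses, 250–1000
Monte-Carlo draws for the House-of-Cards and shuffled-null expectations,
and 1000 genotypes × 3 replicates × ~100 reads for the recovery
experiment.  These sizes keep every oracle exhaustively checkable while
leaving Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

* The noise model treats τ as exact; τ is itself a 3-replicate estimate
  with heavy sampling error, which the sweep's scale factor explores only
  crudely.
* The square census requires all four corners observed, so epistasis
  proportions on sparsely sampled landscapes are conditional on
  observability.
* Walk summaries count a Kimura walk as "reaching" a high peak if it ever
  occupies one, which is the natural analogue of SSWM termination but not
  identical to endpoint statistics.
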