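# Methods

`herdnet` reconstructs proximity interaction networks of a permanently
housed dairy herd from indoor-positioning trajectories and tests their
structure with permutation inference.  This note records the models, the
parameters that matter, and the design choices made where the problem was
genuinely open.

## The detection protocol

An interaction between a dyad (unordered pair of cows) is a *sustained*
proximity event: `window_points = round(t / sample_interval)` consecutive
samples — consecutive meaning timestamps exactly one sample interval
apart — whose inter-cow distances all lie within radius `r`.  Defaults
are `r = 3` m and `t = 60` s, i.e. 6 points at 0.1 Hz; the distance
threshold is inclusive (`<= r`), where ties are measure-zero on real
data.  A *lenient* variant accepts a window when at least a fraction `f`
of its samples are in radius; strict is exactly lenient with `f = 1`,
and the suite verifies that identity exhaustively.

Two counting conventions exist because daily totals alone cannot reveal
which was used to produce any historical dataset:

* **tumbling** (default): scan left to right, count a qualifying window,
  advance past it.  Daily counts are then proportional to sustained
  contact time (one count per 60 s of unbroken contact).
* **sliding**: count every qualifying window position.

Both are first-class and the invariance suite (radius monotonicity,
duration monotonicity, zone nesting, oracle equivalence against naive
window enumeration) covers both.  For strict mode the implementation
reduces to run-length arithmetic on the in-radius mask — a maximal run of
length `L` holds `floor(L / w)` tumbling or `max(L - w + 1, 0)` sliding
windows — which is exactly equivalent to the scan and vectorises over
dyads.

Zone-specific networks (feeding zone `10.5 <= y <= 17.2` m; non-feeding
zone `1.62 <= y <= 10.5` m, `-1.6 <= x <= 58.6` m) filter positions into
the zone dilated by a 3 m buffer before detection, so an interaction is
attributed to a zone only when both animals' samples in the window
survive that zone's filter.  The full barn is the union of the zones.

## Cleaning

Four stages in fixed order, each reporting the fraction of the original
records it removed:

1. **Region filter**: drop fixes beyond a 3 m buffer outside the barn
   rectangle (removes parlour/collecting-yard fixes and gross errors
   while tolerating minor inaccuracy at the walls).
2. **Stuck-run removal**: per cow-day, drop maximal runs of at least
   `min_run = 12` consecutive fixes (2 min) all within `eps = 0.05` m of
   the run's first fix.  No published thresholds exist for this rule;
   these defaults catch repeated-coordinate reset artifacts while
   sparing genuine lying bouts, whose fixes retain sensor jitter far
   above 5 cm.  Unsorted timestamps are rejected, never silently sorted.
3. **Smoothing**: centred unweighted moving average, window 15 samples
   (150 s), applied per contiguous segment; 7 records are lost at each
   segment end and segments shorter than the window are dropped whole.
   Gaps longer than one sample interval break segments so absences
   (milking) do not smear across.
4. **Stationary-day removal**: drop a cow-day when at least 90 % of its
   records fall in a box of diagonal 5 m centred on the day's median
   fix.  The published rule ("relatively stationary for most of a day")
   names no threshold; both numbers are exposed in the config.

Only smoothing alters coordinates; no stage alters a retained record's
identity or timestamp.  Cleaning is nearly idempotent: a second pass
removes the new smoothing edges, and the stuck rule may additionally
clip a small fraction (< 1 % in the suite) because averaging can flatten
genuinely slow segments below the 5 cm threshold.

## Permutation inference

All tests share one p-value rule: `p = #(t_p >= t_o) / q` over `q`
permuted statistics (default 10,000 in the full battery; 1,000 in the
desk-scale studies), with the biased estimator `p = 1/(q+1)` substituted
when no permuted statistic reaches the observed one, so p is never 0.
Two-tailed comparisons (the Wilcoxon) feed the absolute centred rank-sum
statistic through the same rule.  Bonferroni correction is applied per
battery (`p_adj = min(1, p*m)`).

* **Social differentiation** `S`: mean squared deviation of dyadic
  counts from the uniform expectation `E = total / n_dyads`.  The
  ordered double-sum form divided by `n(n-1)` and the dyad-sum form
  divided by `n(n-1)/2` are algebraically identical; the implementation
  uses the unordered form and the suite checks the identity numerically.
  The null redistributes the day's total uniformly over dyads
  (multinomial); per-dyad "differentiated" flags mark squared deviations
  above the null's 95th percentile.  Note the multinomial null tests
  *uniform association*, not "no preference": any bout-structured
  movement produces overdispersed counts, so S rejects on essentially
  every realistic day — including simulated herds with no planted
  preference.  That is the statistic doing its job; the recovery
  question (do the flags land on genuinely preferred dyads?) is answered
  by the enrichment study below.
* **Rank tests**: inter-individual Kruskal–Wallis (groups = cows,
  observations = daily interaction totals) with cow identities shuffled
  within each day — shuffling whole per-cow vectors would merely relabel
  the groups and leave the statistic unchanged; between-day K-W with day
  labels shuffled within each cow; two-group Wilcoxon (lame vs non-lame
  per-cow means) with labels shuffled across cows.  Permuted statistics
  are recomputed on re-ranked data; ties take average ranks.
* **Mantel–Spearman**: Spearman correlation of two matrices' upper
  triangles; the null permutes one matrix's rows and columns
  simultaneously.  Used for temporal stability (consecutive block-
  averaged networks, default 4-day blocks, Bonferroni over the
  comparisons) and attribute assortment (absolute-difference matrices
  for parity, days in milk, and lameness coded 1/0; negative R_s means
  similar animals interact more).  The orientation is one-sided
  (greater), matching the shared p-value rule.

Lameness classes derive from three fortnightly mobility scores (0–3
scale; 2–3 = lame per session): all-NL and dominant-NL sequences are
non-lame, all-L and dominant-L are lame, twice-switching sequences and
any missing score are excluded.

## The synthetic herd generator

No public positioning dataset accompanies the study design, so the
generator is a first-class module with known ground truth.  It emulates:

* 0.1 Hz sampling, day boundaries at midnight, records removed during
  three daily 70-min milking absences (05:00, 13:00, 21:00 centres;
  optionally parlour-located fixes instead);
* barn-confined movement as a semi-Markov bout process per cow-day:
  cubicle rest (mean 55 min), feed-face bouts (30 min, forced after each
  milking when fresh feed arrives), loafing (12 min), with stationary
  Ornstein–Uhlenbeck jitter (sd 0.45 m, 90 s relaxation) around the
  current station;
* social structure through a planted symmetric affinity matrix
  `w_ij = exp(spread * g_ij - effect * d_ij)` (`g` symmetric Gaussian,
  `d` a chosen attribute's difference scaled to [0,1]; positive effect =
  homophily).  Affinity acts through three channels: station adjacency
  (a greedy chain orders cows so high-affinity dyads get neighbouring
  cubicle and feed stations, 2.2 m pitch; with equal affinities the
  order is uniformly random, keeping the null exchangeable), partner
  visits (a rest bout becomes, with probability `social_prob`, a visit
  that shadows a partner's base trajectory at a 1.8 m offset; partners
  are drawn proportional to affinity, and a booking calendar lets each
  host accept one visitor at a time so visits overflow down the affinity
  gradient rather than piling onto one cow), and co-feeding (a feeding
  cow relocates beside a preferred cow already at the feed face);
* sensor corruption: isotropic Gaussian noise with per-axis
  `sigma = CEP50 / sqrt(2 ln 2)` (CEP50 default 1.90 m, the circular
  error probable of a collar sensor on a moving cow), stuck runs of
  exactly repeated coordinates, and isolated far-out-of-barn fixes, all
  logged for cleaning-stage validation.

The ground-truth log records every maximal interval during which a
dyad's *noise-free* distance stays within the contact radius; the suite
verifies the log against a brute-force recomputation and that the
detector recovers every planted contact of at least the protocol
duration on noise-free data.

What the generator does **not** emulate: realistic kinematics (cows jump
between stations; only the OU jitter moves continuously), diurnal
rhythms beyond milking/feeding, entry/exit of animals mid-study,
heat-stress responses, or any coupling between lameness and movement.
Passing tests therefore demonstrate that the pipeline recovers planted
statistical structure under realistic noise — not that any biological
conclusion transfers to a particular real herd.

## Simulation studies and their conditions

The studies run at desk scale: 20-cow herds over 1–2 days, q = 1000,
with sensor noise but no stuck/out-of-barn artifacts, and the smoothing
stage applied before detection (smoothing is what makes strict 6-point
windows survive 1.9 m CEP noise; cleaning's other stages have their own
unit suites).

* **Type-I calibration** (200 null herds, spread = effect = 0): the
  Mantel assortment test (parity differences vs summed interaction
  matrix) and the permuted Wilcoxon (balanced random labels on per-cow
  mean daily interactions) must reject at close to the nominal 5 %.
  Exchangeability holds by construction: with equal affinities the
  station order, visit targets and attributes are all independent
  draws.
* **Power** (100 herds): the planted preference uses
  `effect = -6, spread = 0.1, social_prob = 0.7` on days in milk — a
  *disassortative* plant, because the one-sided (greater) Mantel
  orientation detects positive correlation between interaction counts
  and attribute differences; the mechanism is sign-symmetric, so this
  choice is about test orientation, not biology.  These values were
  fixed once by pilot simulation so the median per-day empirical R_s
  lands near +0.35, and the Bonferroni-adjusted per-herd rejection rate
  is then expected to be essentially 1.
* **Differentiation recovery** (100 herds, spread = 1.2, no attribute
  coupling): per-dyad differentiation flags are computed on unsmoothed
  matrices — in the smoothed high-count regime virtually every dyad
  exceeds the multinomial null (as in any strongly bout-structured
  data), so flags discriminate only in the sparse-count regime.  Flags
  should land on top-decile-affinity dyads at well over twice the
  overall flag rate; the suite requires >= 2x.

## Numerical and interface choices

* Timestamps are epoch seconds internally; ISO-8601 is accepted on
  input.  Records are strictly ordered by (animal, timestamp); duplicate
  timestamps per animal are an input error.
* All matrices are written as square delimited text with animal-id
  headers and empty diagonal cells; positions as five-column CSV
  (animal_id, day_index, timestamp, x_m, y_m).
* Every stochastic stage's generator derives from one master seed
  (SHA-256 of seed:stage), making end-to-end runs byte-identical across
  invocations; the manifest records the config hash and stage seeds.
* The "filtered by mean degree" display networks keep edges with weight
  at or above the mean nonzero edge weight.  The underlying rule is not
  defined anywhere authoritative; this interpretation is confined to
  visualisation output and never feeds inference.
* Mean-degree/clustering, density and components use the binary graph
  (edge iff at least one interaction); no weight threshold beyond >= 1
  is applied.

## Known limitations

* The stuck-run and stationary-day thresholds are conventions, not
  estimates; on other sensor systems they should be re-examined.
* The per-dyad differentiation flag rule (exceedance of the multinomial
  null's 95th percentile) is one reasonable reading of "percentage of
  dyads socially differentiated"; other constructions exist and would
  give different percentages on the same data.
* A manual observation/checking pass, as used in the original cleaning
  of such data, is inherently not reproducible in code; only the
  automated stationary-day rule is implemented.
* The movement model's bout parameters are stand-ins chosen for
  plausible zone occupancy; they are not estimates of any real herd's
  time budget.
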