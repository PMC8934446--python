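# Methods

## Model and conventions

The DP matrix places the first string `a` on the rows (index `i`) and the
second string `b` on the columns (index `j`); cell (i, j) is the cost of
editing `a[:i]` into `b[:j]`.  The column-consuming move carries `w_ins`
(a base of `b` added), the row-consuming move `w_del` (a base of `a`
dropped), the diagonal move 0 or `w_sub`.  Borders are initialised to the
*unweighted* values `max(i, j)` even under weighted schemes: this is
deliberate and is exactly what makes the naive weighted border minimum
(weighted SLD) unreliable — on the 8-mer demonstration pair the weighted
corner is 6 (one insertion at 1 plus one deletion at 5) while the weighted
border minimum collapses to 3.  The axis convention is pinned by requiring
the four demonstration values (unweighted LD 2 / SLD 1, weighted LD 6 /
SLD 3) to emerge jointly in a single convention; it is the unique such
assignment up to matrix transposition.

`N` is treated as an unknown base that matches nothing, itself included.
Inputs are uppercased; characters outside `{A,C,G,T,N}` are rejected.

## Composition inference

The weighted distance is not read off a weighted matrix.  Instead the
*unweighted* matrix is interpreted:

* The border minimum (SLD) is located, considering offsets up to the
  frameshift allowance `f` from the corner.  If it repeats along one
  border, the cell closest to the corner characterises the errors; if it
  occurs on both borders (corner excluded) both candidates are evaluated
  and the cheaper interpretation wins, except that equal insertion and
  deletion weights short-circuit to the rightmost-column candidate.  The
  corner always remains a fallback candidate, so the inferred penalty never
  exceeds the corner's own best decomposition.
* At a candidate cell, net length difference fixes the net indels
  (bottom-row offsets ⇒ deletions, rightmost-column offsets ⇒ insertions);
  the residual unweighted cost `r` is decomposed over substitutions and
  insertion+deletion pairs.  All Pareto decompositions
  `(k pairs, m subs)` with `k = ⌈(r − m)/2⌉`, `m = r … 0` are scored and
  the lowest combined penalty kept.  When `w_ins + w_del < w_sub` this
  deliberately prefers a pair over a substitution, inflating the error
  *count* by one while lowering the *penalty* — a documented and intended
  over-count.

The inference is arithmetic: it uses only border values and positions,
never re-aligning the strings, so on adversarial inputs the reported
composition may not be realisable by an actual edit script (e.g. it may
posit a substitution-to-pair trade the characters cannot support).  Under
unit weights the inferred penalty provably equals the brute-force minimum
over scripts with free tail truncation (property-tested); under general
weights it is bounded above by the corner decomposition.

The bidirectional ("mirrored") distance runs the inference on the strings
as given and on character-reversed copies — reversal converts upstream
frameshift into downstream frameshift — and keeps the cheaper orientation,
forward winning ties.

Two sequences are *linked* (clusterable) when the weighted penalty is
within the weight threshold **and** the unweighted border minimum of the
chosen orientation stays below the termination bound `h = τ + f`.  τ thus
acts through the computability bound, not as a hard cap on the composition
total: compositions inflated by pair-trading may exceed τ while the pair
still links, mirroring the over-count behaviour above.

## Banded computation

`banded_sld` initialises the borders in the traditional manner while their
values stay below `H = max(τ + f, 1)`, then extends the computed region
diagonally, pruning every cell whose value reaches `H` and terminating
with "exceeded" when a whole row offers nothing below the bound.
Correctness argument: step costs are non-negative, so along any path the
running cost is non-decreasing; a path ending below `H` therefore never
visits a cell whose exact value is ≥ `H`, and by induction the first
pruned cell on such a path would have been computed exactly — a
contradiction.  Hence every result below `H` (value *and* positions)
equals the full-matrix scan.  The `max(·, 1)` handles the degenerate
τ = f = 0 case so that identical strings still report 0 rather than
exceeded.

The band spans roughly `2(τ+f)` diagonals, so the cell-count saving over
the full matrix materialises when `τ + f` is small relative to the
sequence length — the regime the method targets (τ = 3, f = 4, 20-mers:
~94 cells vs 441).  For `τ + f` comparable to the length the band covers
the whole matrix and nothing is saved.

## Parameters

| parameter | meaning | default / typical |
|---|---|---|
| `w_ins`, `w_del`, `w_sub` | per-type penalties, inverse to platform frequency | 1/2/4 (insertion-heavy), 2/1/4 (deletion-heavy) |
| `τ` | expected total errors between related sequences | ceil(error rate × length); 3 for 10 % error 20-mers |
| `f` | frameshift allowance, border positions | 15 % of length (20 % for tag extraction from noisy reads), rounded half up |
| weight threshold | max cumulative penalty for a link | from the match-weight histogram (below) |

The weight threshold is determined empirically: score every window of the
data against the probes without thresholds, histogram the match weights,
and take the smallest weight at/after the steepest drop of the count curve
whose cumulative share exceeds 99 %.  "Steepest drop" is operationalised
as the largest decrease between consecutive occupied bins, the empty tail
after the last bin included.

Profiling estimates the weights and τ from reference/read pairs: the pair
is trimmed to the shorter length, the composition inferred with
provisional weights encoding the user's two likelihood hints
(substitution vs indel pair; insertions vs deletions, each
`less`/`more`/`equal`), and bases analysed counted as the reference extent
actually covered (an insertion surplus pushes reference tail bases out of
the window; they are not counted as observed).  Suggested weights: the
majority indel type costs 1, the minority 2 (both 1 when within 20 % of
each other); substitutions cost `w_ins + w_del + 1` unless they dominate.
Suggested τ is the error rate times the target length, rounded up —
errors come in whole numbers.

## Clustering pipeline

All-to-all links (directional, both directions stored since the metric is
asymmetric when `w_ins ≠ w_del`) → candidate cluster per sequence (itself
plus its links) → collapse: smallest candidates first, a candidate sharing
≥ 80 % of its members with a larger one merges into the largest such host
(equal sizes: earlier seed), members exclusive to the smaller candidate
admitted only when within threshold of the host's seed; restart after
every merge until stable → exclusivity: a sequence in several surviving
candidates is assigned to the largest (then earliest) → centroid election:
most members linked, then shortest mean distance, then input order;
members beyond threshold of the elected centroid return to the pool →
singleton rescue: nearest within-threshold centroid, equidistant
singletons joining the larger cluster.  The pipeline is deterministic in
the input order; sequences must be of uniform length.

For comparison experiments the same pipeline runs with two degenerate
metrics: plain forward unweighted SLD and plain corner LD, both linking at
distance ≤ τ.

Evaluation matches reference to experimental clusters by contained
centroid, falling back to maximum member overlap (each experimental
cluster used once, larger overlaps first).  Sensitivity is
`100·(1 − p/m)` (`p` = reference members missed, `m` = reference size);
specificity `100·(t − u)/t` with `u` the *false inclusions* — the
alternative reading of `u` as "reference members left unclustered" is
selectable (`u_definition="unclustered"`) but not the default, because
tools that leave most sequences unclustered would then score near zero
specificity while they are conventionally reported at 100 %.  Qualified
clusters have ≥ 20 % sensitivity and survive the smallest size cutoff
limiting the cluster count to the expected number.

## Synthetic benchmarks

Centroids are uniform random 20-mers rejection-sampled until every pair is
separated in the metric the clustering actually uses: classic corner
distance *and* the frameshift-capped border minima of both orientations
must exceed the floor (8).  Corner-only separation is insufficient — a
pair separated only at the corner can fall inside the clustering threshold
through a truncated reading and let a whole cluster bleed into a
neighbour, which is observable as equidistant/orphaned singletons in noisy
runs and as outright cluster absorption in error-free ones.

Errors are injected i.i.d. per base: an insertion may precede each base
(and the final slot), the base itself is then deleted or substituted at
the configured rates.  The presets mirror measured aggregate simulator
profiles — 11.10 % total with 66.35 % insertions / 33.70 % deletions
(PacBio-like) and 10.13 % total with 30.30 % / 69.70 % (Nanopore-like) —
but model no homopolymer or sequence context, no chimeras and no quality
scores.  Passing benchmarks therefore demonstrates the metric and pipeline
under type-biased indel noise, not simulator- or instrument-faithful read
physics.  Each read records its true centroid and a replayable edit log.
Non-tandem reads are emitted at exactly the centroid length, emulating a
probe-length window cut from a tandem repeat (a short copy is completed by
the start of the following copy; a long one is truncated): the clustering
input must be uniform-length.

Benchmark layouts follow the standard series (4×125 … 50×10 reads).  Test
and demonstration runs use the mid-sized layouts (e.g. 10 clusters × 20
copies, 5 seeds) — large enough for stable averages, small enough to keep
the whole suite fast.

## Known limitations

* At ~10 % error density the unit-LD minimal script coincidentally merges
  ~5 % of injected events (an inserted base equal to an adjacent deleted
  base is literally invisible), so profiled rates sit slightly below the
  injection probabilities; recovery is validated against the realised
  injected counts.
* The composition inference is content-blind (see above); its penalties
  are exact for unit weights and upper-bounded otherwise.
* Variable-length input is not supported; trim or window reads first.
* The all-to-all matrix is O(n²) in the number of sequences; the banded
  computation and the vectorised batch filter keep the constant small, but
  very large datasets will still be slow.
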