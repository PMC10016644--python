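# Methods

This note records the models implemented in `pedgroups`, the assumptions
behind them, the parameters that matter, and the design decisions taken
where the problem left genuine freedom.

## Trajectory model and data quality

A trajectory is one pedestrian's positions on an integer frame clock
(strictly increasing frames, planar metres, fixed frame rate; the default
tooling assumes 10 fps but every operation takes the rate from the data).
Frames may be missing inside a track: stereo sensors lose pedestrians and
re-assign a new id on re-detection, so intra-id gaps are short and are kept
as-is — no interpolation, smoothing or id re-stitching is attempted.

Quality control checks endpoint plausibility: a complete trajectory starts
and ends in an entry region (stair or elevator mouth), an edge region (the
platform–train interface) or a lateral boundary of the observed strip.
Membership is boundary-inclusive with a snap tolerance of 0.5 m to absorb
sensor jitter at track ends. Trajectories observed for less than 20 s
(inclusive boundary: exactly 20 s is kept) are excluded from analysis —
shorter windows do not support a stable assessment of pairwise relations.
The 20 s minimum is applied to the total track duration, not to time spent
in any sub-region.

## Passenger classification

Boarding: first position in an entry region and last position in an edge
region. Alighting: the reverse. Everything else — typically fragmented
tracks — is `unknown`. Group detection is restricted to boarding
passengers by default: alighting passengers cross the platform in seconds
on near-identical straight paths, which makes social relations
unassessable from proximity.

## The pair criterion

For a candidate pair, `t_sim = min(last_i, last_j) − max(first_i,
first_j) + 1` is the inclusive count of frames during which both tracks
exist. `t_contact` and `t_personal` count co-sampled frames with distance
≤ 1.5 m and ≤ 1.0 m respectively (boundary inclusive). The thresholds have
behavioural meaning: 1.5 m is a conversational/contact distance (and the
mode of pairwise-distance densities on platforms), 1.0 m is the personal
zone that unrelated adults do not share for long. The pair is social when
`t_contact ≥ α·t_sim` and `t_personal ≥ β·t_sim`, defaults α = 0.85,
β = 0.40.

Numerical choices:

- Frames inside the shared window where either track is unsampled count
  toward `t_sim` but never toward contact. This conservatively lowers
  detection for fragmented tracks — preferable to inflating contact
  fractions from partial evidence.
- Pairs with no temporal overlap (`t_sim ≤ 0`) never qualify; the
  threshold inequalities would be vacuously true at `t_sim = 0`.
- The comparisons are boundary-inclusive with a relative 1e-9 float guard,
  so that e.g. 85 contact frames out of 100 qualify at α = 0.85 despite
  binary rounding of the product. The guard is four orders of magnitude
  below the 0.05 parameter granularity and cannot flip a genuinely
  failing point.
- Distances are Euclidean, compared only at exactly matching frame
  indices; no interpolation.

## Candidate pairs by Delaunay triangulation

Computing all-pairs distances per frame scales with N²; members of a
social group, however, are mutual nearest neighbours, so it suffices to
examine the Delaunay edges of the per-frame position sets (O(N log N)).
The candidate set is the union of Delaunay edges over all frames — the
most permissive accumulation, minimising misses relative to brute force.
Degenerate frames (fewer than 3 pedestrians, collinear or duplicated
positions) fall back to all pairs for that frame: correctness over speed
for rare frames. A `stride` knob evaluates only every k-th frame as a
documented approximation; all shipped results use stride 1.

The equivalence with the brute-force pipeline is exact in the regime the
method targets (clusters separated by more than the contact distance) and
is enforced by tests; it is not guaranteed in dense crowds, where the
criterion itself is invalid anyway (proximity no longer implies relation
once local density exceeds roughly 0.5–1 /m²).

## Group assembly

Qualifying pairs form a graph; groups are its connected components.
The reported group size is the maximum number of members simultaneously
present (sweep over presence intervals), not the number of member ids —
fragmented tracks can attach several ids to one person, and the maximum
co-presence guards against that overcounting. Components are ordered by
smallest member id; the whole pipeline is deterministic.

## Parameter study

Ground truth is a set of pedestrian ids annotated as group members by two
independent raters; their agreement is reported as intersection over
union (this denominator reproduces the published 90.7% from the published
counts 154, 153 and 146, and is therefore adopted), and the consensus
(intersection) is the truth set. Every id outside the consensus is treated
as an individual, so any detection of it counts as a false positive —
a deliberately harsh convention that penalises members missed by both
raters.

The grid spans [0, 1]² in steps of 0.05. Contact statistics are computed
once per candidate pair and reused: each grid point is a pure threshold
check, which guarantees cross-grid consistency and makes the detected
sets nested under tightening fractions (hence the zero-false-positive
region is closed toward larger α, β). Selection is the zero-false-positive
point maximising detected members; ties break toward larger α, then larger
β — the most conservative of the equally good points. If no grid point is
free of false positives the result is an explicit "no admissible
parameters", never a least-bad guess.

## Speed, waiting and occupancy

Speed is a central displacement difference over Δt′ = 50 frames, divided
by Δt′ expressed in seconds so the result is m/s (a divisor in frames
would make the 0.4 m/s threshold meaningless). Speed is undefined at
frames lacking either window endpoint — near track ends and sensor gaps —
rather than computed with a shrunken window, avoiding edge bias; waiting
time sums only defined frames, and per-pedestrian mean speeds average only
defined frames. Waiting is strict: `v < 0.4 m/s`. The threshold is the
separating minimum between the waiting (~0.2 m/s) and walking (~1.2 m/s)
modes of platform speed distributions and is exposed as a parameter rather
than re-estimated. Waiting-time bins are left-closed at 2, 5 and 10 min.

Occupancy tiles are half-open squares of 0.5 m (about one shoulder width),
snapped to the lower-left corner of the measurement-area bounding box;
positions on the top/right grid boundary belong to the last tile, and
positions outside the grid are excluded but tallied in an overflow
diagnostic. The per-tile value is waiting pedestrian-frames divided by the
total observation frames N_f — a sum over pedestrians, so tiles shared by
several waiting people can exceed 1; such tiles are flagged in metadata,
not clipped. The conservation identity (sum of tile counts = total
in-grid waiting pedestrian-frames) is exact integer accounting and is
tested as such.

## The synthetic generator

The generator produces the statistical structure the detector assumes, on
a schematic 50 m × 10 m island platform (two stair blocks, two elevators,
an information board, doors along both long edges). Boarding parties
arrive in a Poisson stream (default 6 /min over 45 min), with party sizes
drawn from a non-increasing law over 1..6 (default 80% singletons, 12%
pairs, then 5, 2, 0.7, 0.3%); alighting pedestrians (default 6 /min) cross
without stopping. A party walks at 1.2 m/s from an entry to a waiting
anchor, waits (30 s minimum plus an exponential tail, mean 90 s), then
walks to the nearest door. Group members share the anchor, stand on a
circle with ~0.5 m between neighbours (circles preserve eye contact, and
larger groups therefore occupy more area), and arrive and depart together.
Positional jitter is a bounded AR(1) process (stationary sd 0.1 m, clipped
at 3.5 sd, decorrelation ~1 s). Anchor placement is biased by party size —
large groups settle 2–6 m from their entry, individuals drift 4–12 m out
toward the stair sides — echoing observed waiting-place preferences.

Two construction rules make ground truth identifiable by design:

1. **Anchor separation.** Waiting anchors of co-present parties are at
   least 4 m apart. With bounded jitter and formation radii ≤ 0.5 m, two
   waiting strangers can never come within the 1.5 m contact distance.
2. **Minimum stranger overlap.** Co-presence windows of unrelated parties
   are either empty or at least 25 s long (arrivals are delayed a few
   seconds when needed, parties that cannot be scheduled are dropped).
   Since each agent walks for at most ~15 s in total, walking encounters
   cannot reach the 85% contact fraction over any admissible shared
   window — so stranger pairs provably fail the validated criterion, and
   precision 1.0 at (0.85, 0.40) is a property of the construction, not a
   tuning outcome.

These rules mirror the low-density validity domain of the method itself;
the generator refuses to emulate regimes the criterion cannot handle.
What the generator does **not** model: collision avoidance or social-force
interactions, density-dependent behaviour, train-timetable bursts,
platform furniture use, or annotator noise in ground truth. Passing tests
therefore demonstrate correctness of the algorithmic pipeline under the
method's stated assumptions — not performance on crowded real platforms.

Track fragmentation emulates sensor loss: `fragmentation_prob` is the
expected fraction of *output* tracks that are fragments, implemented by
cutting each track with probability q = p/(2−p) (each cut turns one track
into two), at a frame where the pedestrian is away from any plausible
start/end region so fragments are genuinely incomplete. Per-track draws
are made in fixed id order, so cut sets are nested across probabilities
under one seed and recall degradation is genuinely monotone. At p = 0.22
the expected complete-trajectory fraction is (1−q)/(1+q) ≈ 0.78, the
regime reported for real stereo-sensor installations.

All randomness flows from one integer seed through a PCG64 generator;
identical configuration and seed reproduce scenarios bit for bit.

## Problem sizes used in shipped checks

The default test scenario covers 45 minutes at 10 fps with ~580
trajectories and ~45 true groups; the oracle-equivalence checks use 12
scenes of 250 frames with up to 30 pedestrians each. These sizes give
binomial confidence bands tight enough for the fragmentation and
size-law checks while keeping the full suite fast.

## Known limitations

- The criterion is only valid at low densities; in crowds, proximity
  stops implying social relation and both thresholds and fractions would
  need revalidation. No correction is attempted.
- Alighting passengers are unassessable by construction; movement-
  correlation criteria are out of scope.
- `t_sim` is computed from track endpoints and ignores interior gaps, so
  heavily fragmented tracks are under-detected (by design, conservatively).
- The schematic platform geometry is proportioned after a typical
  observed layout, not surveyed; geometry files for real sites can be
  supplied as JSON.
- Heatmap rendering is presentation-only and untested beyond smoke level.
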