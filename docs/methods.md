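# Methods

## Problem and model

Web genome browsers stack tracks (dataset + display options) vertically in a
*track container* aligned to the reference. With hundreds of registered
datasets only a handful are informative at any one locus, and keeping the
screen relevant normally costs constant manual toggling. dynatrack implements
the automatic alternative as a pure, headless engine: every managed signal
track is registered together with the companion feature file describing where
its signal is significant, and the engine uses those features — a priori
knowledge produced upstream by peak calling or equivalent — to decide, per
window, which tracks to show.

**Interestingness.** A track is *locus-specific interesting* in window
[s, e) iff it owns a feature [s', e') on the same chromosome with
s' < e and e' > s. The criterion is deliberately minimal: at least one base
pair of overlap, no minimum-overlap fraction, no score threshold, strand
ignored. Separating signal from background is the upstream pipeline's job;
changing the peak caller's stringency, not the browser's query, is the
supported way to tune sensitivity.

**Container composition** is a pure function of (registry, classification,
previous state). Static tracks form a fixed backbone in configured position
order. Automatic groups display the rank-ordered prefix of their interesting
list; manual groups keep their current block and park the fresh
classification in `pending` until the user applies it; disabled groups are
copied verbatim. Group blocks are contiguous, placed directly below their
anchor; anchor chains resolve transitively and are acyclic by load-time
validation (depth-first cycle detection with the offending cycle named in the
error). Blocks anchored on the same target stack in declaration order.
Composing twice with the same inputs is a fixed point, which makes replay
and golden-file testing meaningful.

**Caps and overflow.** `max_visible` bounds one group; `global_max_visible`
bounds the sum of group-managed visible tracks. When both bind, groups are
processed in container placement order and each takes
min(own cap, remaining budget); later groups may receive zero slots. This
allocation policy is a design choice — any deterministic rule satisfies the
reproducible-experience requirement, and placement order is the one a user
can read directly off the screen. Static tracks never count against the
global budget: the cap exists to bound automatic additions, not the user's
own backbone. `overflow[g]` is true iff the group shows fewer interesting
tracks than exist; `global_overflow` is true iff the global budget (rather
than a group's own cap) caused a truncation.

**Carousel.** With N interesting tracks and V visible slots (N > V), each
rotation advances the window by step = ⌈V/2⌉ on the ring, replacing that many
visible tracks. Ceiling rather than floor guarantees progress at V = 1. The
window slides forward (the later half of the previous view is retained), so
repeated clicks read downward through the predefined order; rotation is
forward-only, with wrap-around supplying eventual return after
N / gcd(N, step) clicks — the first recurrence of the initial view, since
distinct offsets of a size-V (< N) cyclic window are distinct sets. The
offset resets to zero whenever a group is recomposed for a new window: a
rotation sequence is only meaningful against a fixed interesting list.

## Parameters

| Parameter | Where | Default | Meaning |
|---|---|---|---|
| `mode` | group | `automatic` | automatic / manual / disabled browsing |
| `anchor` | group | none | static track or group the block sits below |
| `max_visible` | group | unlimited | per-group visible cap (≥ 1) |
| `global_max_visible` | registry | unlimited | total managed-visible cap (≥ 1) |
| `rank` | track set | — | display order within the group, unique |
| `position` | static track | — | backbone order, unique |

Region strings are 1-based inclusive (`chr2R:8794209-8812865`, thousands
separators tolerated), converted once at the parsing boundary; all internal
coordinates are 0-based half-open, matching BED arithmetic. BED is consumed
as-is; GFF3 start is decremented on read; a 1-based single-base GFF3 feature
becomes a 1 bp half-open interval, and any row whose converted interval is
empty or reversed is a format error naming the line.

## Synthetic data

The fixture generator emulates a small deployment: per track a BED of
uniformly placed peak-like features and a bedGraph of constant-height
rectangles over exactly those features (zero elsewhere, encoded by omission),
a static genes track, and a registry wiring the tracks into groups — by
default groups of seven tracks, the size of the demo walkthrough group,
with 200–2000 bp features on a chromosome the length of Drosophila chr2R.
All randomness flows from one `numpy` generator seed and output files are
written in sorted order, so identical seeds give byte-identical trees.

What the generator does **not** emulate: realistic peak clustering or
signal-noise structure (features are uniform, signal is rectangular),
overlapping bedGraph intervals from replicate merging, multi-sample
co-occurrence patterns, or feature files that disagree with their signal
files. Passing tests therefore demonstrate the correctness of the selection,
ordering, capping and rotation logic — not anything about biological signal;
the engine never inspects signal values when classifying, so this is the
logic that exists to be tested.

The two-window walkthrough fixture is engineered, not sampled: seven tracks
anchored below a genes track, all featured in `chr2R:8794209-8812865`, and
only ranks 2, 4 and 7 featured in `chr2R:8878094-8896750`, 84 kb downstream.
Navigating between the windows must shrink the container from
`[genes, t1..t7]` to `[genes, t2, t4, t7]`.

## Numerical and design choices

- **Interval structure.** Queries go through per-chromosome interval trees
  (`intervaltree`); the contract is oracle equivalence with a linear scan,
  and the test suite enforces it on randomized fixtures with an independent
  brute-force scan over the raw BED rows.
- **Unresolvable anchors degrade, never fail.** If a block's anchor target
  cannot be found at compose time the block is appended at the container end
  and a diagnostic is recorded in the state's `log`; navigation must never
  abort mid-session. (After load-time validation this path is unreachable
  from a file-loaded registry, but the engine stays total.)
- **Manual-mode summary counts.** A manual group's stale block may show
  tracks that are no longer interesting; `n_visible` counts only
  visible-and-interesting tracks so `n_visible + n_hidden = n_interesting`
  holds in every mode.
- **One group per track set.** A track set belongs to exactly one group
  (`group_id`); membership in several groups would break block contiguity
  and the no-duplicates container invariant.
- **Re-sorting on navigation.** A track that stays interesting across a
  navigation step is re-sorted to its rank position rather than keeping its
  screen position: the display order within a group is pre-defined, and rank
  order is the only order the engine ever emits at offset zero.
- **Canonical JSON.** States and summaries serialize with sorted keys, no
  insignificant whitespace and an explicit version field; SVG output pins
  `svg.hashsalt` and drops the date so renders are byte-deterministic.

## Scale of the shipped checks

The bundled verification runs at deliberately modest sizes chosen to exercise
every rule many times over while keeping the loop instant: 20 random
deployments (≤ 50 tracks, ≤ 5000 features) × 200 windows for oracle
equivalence; three 100-step random navigation traces over five groups mixing
all three modes with both cap types active; the full carousel grid
1 ≤ V < N ≤ 40 (780 pairs, every rotation until first recurrence); and a
doubled same-seed pipeline run for byte-level determinism. The engine itself
has no size-dependent behaviour — the same code paths run at any scale.

## Limitations

- No browser integration: rendering is a verification surrogate (fixed panel
  heights, no zoom, no styling), not a display server.
- bigWig is read-only optional via pyBigWig; fixtures are always plain text.
- The carousel has a single forward control; there is no reverse rotation.
- Classification is binary per track; partial-overlap weighting or
  score-aware ranking within a window is out of scope.
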