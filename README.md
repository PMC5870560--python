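# dynatrack

Headless engine for **dynamic track display** in genome browsers: given
hundreds of registered signal/feature track pairs and a genomic window, it
decides which tracks are informative there, and how they are ordered, grouped,
anchored and capped on screen — including carousel rotation through the
overflow. It is aimed at people building or testing browser front-ends and at
bioinformaticians who want the track-selection logic itself to be scriptable
and verifiable without a browser.

## The model

A *dependent track set* pairs a quantitative signal dataset (bedGraph/bigWig,
e.g. ChIP-seq or 4C-seq coverage) with its *companion feature dataset*
(BED/GFF3, e.g. a peak list) that marks the regions of significant signal.
All companion features are compiled into one aggregate interval index. For a
window *W* = [s, e) on chromosome *c*, a managed track *t* is
**locus-specific interesting** iff it owns at least one feature [s', e') on
*c* with s' < e and e' > s (half-open overlap, ≥ 1 bp; no score threshold —
signal/background separation is delegated to the upstream peak caller);
otherwise it is **locus-specific empty**.

The track container is then rebuilt under these rules:

- **static tracks** (not managed) keep their configured positions, untouched;
- each **automatic** group shows the rank-ordered prefix of its interesting
  tracks, bounded by the group cap `max_visible` and the remaining
  `global_max_visible` budget (static tracks don't count against it);
- a group's tracks always form one **contiguous block**, placed immediately
  below its **anchor** (a static track or another group; the anchor relation
  is acyclic) or appended after the backbone when unanchored;
- **manual** groups keep their block; the fresh classification is parked as
  *pending* until explicitly applied; **disabled** groups are ignored;
- truncation sets a per-group **overflow** flag (the "data hidden" cue);
- **carousel rotation** through N > V interesting tracks advances the visible
  window of size V by ⌈V/2⌉ positions on the ring per click, so half the
  visible tracks are swapped following the predefined order; the initial view
  first recurs after N / gcd(N, ⌈V/2⌉) rotations.

## Worked example

The bundled demo deployment has a static *genes* track and one automatic
seven-track group anchored below it, with every track featured in
`chr2R:8794209-8812865` and only the tracks ranked 2, 4 and 7 featured
84 kb away in `chr2R:8878094-8896750`:

```sh
python - <<'EOF'
from pathlib import Path
from dynatrack import generate_demo_fixtures, run_navigation
import json
reg = generate_demo_fixtures("demo")
states, summary = run_navigation(reg, "demo/script.json", "demo/nav")
for p in states:
    print([e[0] for e in json.loads(p.read_text())["container"]])
print(summary.read_text().strip())
EOF
```

prints

```
['genes', 't1', 't2', 't3', 't4', 't5', 't6', 't7']
['genes', 't2', 't4', 't7']
{"any_overflow":false,"per_group":{"g1":{"n_hidden":0,"n_interesting":3,"n_visible":3}},"total_visible":4,"version":1}
```

First window: all seven managed tracks are interesting, so the container shows
the genes backbone followed by the whole group. After navigating 84 kb
downstream only t2, t4 and t7 still have features there; the other four are
removed automatically. The summary is what a front-end widget would display:
3 interesting, 3 visible, 0 hidden, no overflow. `dynatrack render` (or
`dynatrack.render_view`) draws any such state as an SVG with one panel per
container entry.

The same flow is available from the shell:

```sh
dynatrack simulate --seed 1 --groups 2 --tracks-per-group 7 --features 20 --out fx
dynatrack index    --registry fx/registry.json --out fx/index.json
dynatrack nav      --registry fx/registry.json --script script.json --out nav
dynatrack render   --registry fx/registry.json --state nav/state_001.json \
                   --region chr2R:8794209-8812865 --out view.svg
```

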