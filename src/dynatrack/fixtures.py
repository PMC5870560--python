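"""Deterministic synthetic fixtures: feature files, signal files, registries.

The generator emulates the data a browser deployment would register: per
track one BED file of peak-like features (uniformly placed, non-degenerate)
and one bedGraph of constant-height rectangles over those features (zero
elsewhere, encoded by omission as usual for bedGraph), plus one static
"genes" BED and a registry JSON wiring everything into groups.  Identical
seeds produce byte-identical directory trees, which makes golden-file tests
and end-to-end determinism checks possible.

Defaults mirror a small but realistic deployment: a handful of groups of
seven tracks each (the size of the demo walkthrough group), peak widths
of 200–2000 bp on a chromosome the size of Drosophila chr2R.

:func:`generate_demo_fixtures` builds the engineered two-window walkthrough:
a genes backbone track, one automatic seven-track group anchored below it,
every track featured in the first window and only tracks ranked 2, 4 and 7
featured in a second window 84 kb away on the same chromosome.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .datamodel import Registry, load_registry_file

# dm6 chr2R length
DEFAULT_CHROM_SIZES = {"chr2R": 25_286_936}

DEMO_WINDOW_1 = "chr2R:8794209-8812865"
DEMO_WINDOW_2 = "chr2R:8878094-8896750"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic deployment."""

    seed: int
    n_groups: int = 2
    tracks_per_group: int = 7
    features_per_track: int = 20
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES)
    )
    feature_length_range: tuple[int, int] = (200, 2000)
    # optional registry knobs, exercised by layout/cap tests
    group_max_visible: Optional[int] = None
    global_max_visible: Optional[int] = None
    mode_cycle: tuple[str, ...] = ("automatic",)

    def __post_init__(self) -> None:
        lo, hi = self.feature_length_range
        if min(self.n_groups, self.tracks_per_group, self.features_per_track) < 1:
            raise ValueError("all counts must be >= 1")
        if not (1 <= lo <= hi):
            raise ValueError("feature_length_range requires 1 <= min <= max")
        if any(size < 1 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be >= 1")


def _write_bed(path: Path, rows: list[tuple[str, int, int, str]]) -> None:
    rows = sorted(rows)
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def _write_bedgraph(path: Path, rows: list[tuple[str, int, int, float]]) -> None:
    rows = sorted(rows)
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def _random_features(rng: np.random.Generator, spec: FixtureSpec,
                     label: str) -> list[tuple[str, int, int, str]]:
    chroms = sorted(spec.chrom_sizes)
    lo, hi = spec.feature_length_range
    rows = []
    for k in range(spec.features_per_track):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        size = spec.chrom_sizes[chrom]
        length = min(int(rng.integers(lo, hi + 1)), size)
        start = int(rng.integers(0, size - length + 1))
        rows.append((chrom, start, start + length, f"{label}_f{k}"))
    return rows


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a complete synthetic deployment; return the registry JSON path.

    Layout under ``out_dir``: ``genes.bed`` (static backbone), per track
    ``<id>.bed`` + ``<id>.bedgraph``, and ``registry.json``.  The first group
    is anchored below the genes track; a second group, when present, is
    anchored below the first; further groups are unanchored.  Group modes
    cycle through ``spec.mode_cycle``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = _random_features(rng, spec, "gene")
    _write_bed(out / "genes.bed", genes)

    groups = []
    track_sets = []
    for gi in range(1, spec.n_groups + 1):
        gid = f"g{gi}"
        if gi == 1:
            anchor = "genes"
        elif gi == 2:
            anchor = "g1"
        else:
            anchor = None
        entry: dict = {
            "id": gid,
            "mode": spec.mode_cycle[(gi - 1) % len(spec.mode_cycle)],
        }
        if anchor is not None:
            entry["anchor"] = anchor
        if spec.group_max_visible is not None:
            entry["max_visible"] = spec.group_max_visible
        groups.append(entry)
        for ti in range(1, spec.tracks_per_group + 1):
            tid = f"{gid}_t{ti}"
            feats = _random_features(rng, spec, tid)
            _write_bed(out / f"{tid}.bed", feats)
            heights = rng.integers(1, 101, size=len(feats))
            _write_bedgraph(
                out / f"{tid}.bedgraph",
                [(c, s, e, float(h)) for (c, s, e, _), h in zip(feats, heights)],
            )
            track_sets.append(
                {
                    "id": tid,
                    "signal_path": f"{tid}.bedgraph",
                    "feature_path": f"{tid}.bed",
                    "group_id": gid,
                    "rank": ti,
                }
            )

    doc: dict = {
        "static_tracks": [{"id": "genes", "path": "genes.bed", "position": 0}],
        "groups": groups,
        "track_sets": track_sets,
    }
    if spec.global_max_visible is not None:
        doc["global_max_visible"] = spec.global_max_visible
    registry_path = out / "registry.json"
    registry_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return registry_path


def load_fixture_registry(out_dir: str | Path) -> Registry:
    return load_registry_file(Path(out_dir) / "registry.json")


def generate_demo_fixtures(out_dir: str | Path) -> Path:
    """Write the engineered two-window walkthrough; return the registry path.

    One static genes track, one automatic group of seven tracks (``t1``–``t7``,
    ranks 1–7) anchored below it.  All seven tracks carry a feature inside
    window ``chr2R:8794209-8812865``; only ``t2``, ``t4`` and ``t7`` carry one
    inside ``chr2R:8878094-8896750`` (84 kb downstream).  Navigating from the
    first window to the second therefore shrinks the container from
    ``[genes, t1..t7]`` to ``[genes, t2, t4, t7]``.

    A ready-made navigation script visiting both windows is written next to
    the registry as ``script.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 0-based half-open images of the two display windows
    w1 = (8_794_208, 8_812_865)
    w2 = (8_878_093, 8_896_750)

    _write_bed(out / "genes.bed", [
        ("chr2R", w1[0] + 2_000, w1[0] + 9_000, "geneA"),
        ("chr2R", w2[0] + 3_000, w2[0] + 8_000, "geneB"),
    ])

    track_sets = []
    in_w2 = {2, 4, 7}
    for rank in range(1, 8):
        tid = f"t{rank}"
        feats = [("chr2R", w1[0] + 1_000 * rank, w1[0] + 1_000 * rank + 600,
                  f"{tid}_w1")]
        if rank in in_w2:
            feats.append(("chr2R", w2[0] + 1_000 * rank,
                          w2[0] + 1_000 * rank + 600, f"{tid}_w2"))
        else:
            # a feature far from both windows: the track exists genome-wide
            feats.append(("chr2R", 1_000_000 + 10_000 * rank,
                          1_000_000 + 10_000 * rank + 600, f"{tid}_far"))
        _write_bed(out / f"{tid}.bed", feats)
        _write_bedgraph(
            out / f"{tid}.bedgraph",
            [(c, s, e, float(10 * rank)) for c, s, e, _ in feats],
        )
        track_sets.append(
            {
                "id": tid,
                "signal_path": f"{tid}.bedgraph",
                "feature_path": f"{tid}.bed",
                "group_id": "g1",
                "rank": rank,
            }
        )

    doc = {
        "static_tracks": [{"id": "genes", "path": "genes.bed", "position": 0}],
        "groups": [{"id": "g1", "mode": "automatic", "anchor": "genes"}],
        "track_sets": track_sets,
    }
    registry_path = out / "registry.json"
    registry_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    (out / "script.json").write_text(
        json.dumps(
            {"steps": [{"goto": DEMO_WINDOW_1}, {"goto": DEMO_WINDOW_2}]},
            indent=2,
        )
        + "\n"
    )
    return registry_path
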