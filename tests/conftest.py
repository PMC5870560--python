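"""Shared fixtures: in-memory registries and on-disk synthetic deployments."""
from __future__ import annotations

import json
from pathlib import Path

import pytest

from dynatrack import Registry, load_registry


def write_deployment(
    tmp_path: Path,
    tracks: dict[str, dict],
    groups: list[dict],
    statics: list[dict] | None = None,
    global_max_visible: int | None = None,
) -> Registry:
    """Write BED files + registry JSON under ``tmp_path`` and load it.

    ``tracks`` maps track id -> {"group": gid, "rank": int,
    "features": [(chrom, start, end), ...]}.
    """
    statics = statics if statics is not None else [
        {"id": "genes", "path": "genes.bed", "position": 0}
    ]
    for s in statics:
        (tmp_path / s["path"]).write_text("")
    track_sets = []
    for tid, spec in tracks.items():
        bed = tmp_path / f"{tid}.bed"
        bed.write_text(
            "".join(f"{c}\t{s}\t{e}\t{tid}\n" for c, s, e in spec["features"])
        )
        (tmp_path / f"{tid}.bedgraph").write_text(
            "".join(f"{c}\t{s}\t{e}\t1\n" for c, s, e in spec["features"])
        )
        track_sets.append(
            {
                "id": tid,
                "signal_path": f"{tid}.bedgraph",
                "feature_path": f"{tid}.bed",
                "group_id": spec["group"],
                "rank": spec["rank"],
            }
        )
    doc: dict = {"static_tracks": statics, "groups": groups, "track_sets": track_sets}
    if global_max_visible is not None:
        doc["global_max_visible"] = global_max_visible
    (tmp_path / "registry.json").write_text(json.dumps(doc))
    return load_registry((tmp_path / "registry.json").read_text(), base_dir=tmp_path)


def make_registry_in_memory(
    n_tracks: int,
    group_id: str = "g1",
    mode: str = "automatic",
    max_visible: int | None = None,
    global_max_visible: int | None = None,
    anchor: str | None = None,
) -> Registry:
    """A single-group registry whose data files are never read.

    Useful for exercising composition and carousel logic directly from a
    hand-built classification.
    """
    doc: dict = {
        "static_tracks": [{"id": "genes", "path": "genes.bed", "position": 0}],
        "groups": [
            {
                "id": group_id,
                "mode": mode,
                **({"anchor": anchor} if anchor else {}),
                **({"max_visible": max_visible} if max_visible else {}),
            }
        ],
        "track_sets": [
            {
                "id": f"t{i}",
                "signal_path": f"t{i}.bedgraph",
                "feature_path": f"t{i}.bed",
                "group_id": group_id,
                "rank": i,
            }
            for i in range(1, n_tracks + 1)
        ],
    }
    if global_max_visible is not None:
        doc["global_max_visible"] = global_max_visible
    return load_registry(json.dumps(doc))


@pytest.fixture
def seven_track_registry(tmp_path: Path) -> Registry:
    """A genes backbone plus one seven-track automatic group anchored below it,
    shaped like the demo walkthrough: all tracks featured in window 1,
    only ranks 2, 4 and 7 featured in window 2."""
    w1, w2 = (8_794_208, 8_812_865), (8_878_093, 8_896_750)
    tracks = {}
    for rank in range(1, 8):
        feats = [("chr2R", w1[0] + 1000 * rank, w1[0] + 1000 * rank + 500)]
        if rank in (2, 4, 7):
            feats.append(("chr2R", w2[0] + 1000 * rank, w2[0] + 1000 * rank + 500))
        tracks[f"t{rank}"] = {"group": "g1", "rank": rank, "features": feats}
    return write_deployment(
        tmp_path,
        tracks,
        groups=[{"id": "g1", "mode": "automatic", "anchor": "genes"}],
    )
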