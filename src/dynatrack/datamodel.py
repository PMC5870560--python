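"""Registry of static tracks, dependent track sets and track groups.

A *dependent track set* pairs a quantitative signal dataset (bedGraph/bigWig)
with the companion feature dataset (BED/GFF3) that marks its regions of
significant signal.  Track sets are organised into *track groups*, each with a
browsing mode (``automatic``, ``manual`` or ``disabled``), an optional anchor
(a static track or another group below which the group's block is always
placed) and an optional visibility cap.  *Static tracks* form the fixed
backbone of the display and are never managed automatically.

The whole registry is declared in a single JSON document; see
``schemas/registry.schema.json`` for the documented shape.  User-facing region
strings are 1-based inclusive (the genome-browser convention); everything
internal is 0-based half-open, matching BED arithmetic.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigSemanticsError, ConfigSyntaxError, RegionSyntaxError

MODES = ("automatic", "manual", "disabled")


class GenomicWindow(BaseModel):
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    model_config = ConfigDict(frozen=True)

    chrom: str
    start: int
    end: int

    @field_validator("chrom")
    @classmethod
    def _chrom_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("chrom must be non-empty")
        return v

    @field_validator("end")
    @classmethod
    def _ordered(cls, v: int, info) -> int:
        start = info.data.get("start")
        if start is not None and not (0 <= start < v):
            raise ValueError("window requires 0 <= start < end")
        return v

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # 1-based inclusive, for display
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class TrackSet(BaseModel):
    """A signal dataset registered together with its companion feature dataset."""

    model_config = ConfigDict(frozen=True)

    id: str
    signal_path: str
    feature_path: str
    group_id: str
    rank: int = Field(ge=0)

    @field_validator("signal_path", "feature_path")
    @classmethod
    def _path_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("path must be non-empty")
        return v


class StaticTrack(BaseModel):
    """A manually controlled track, never auto-added or auto-removed."""

    model_config = ConfigDict(frozen=True)

    id: str
    path: str
    position: int = Field(ge=0)


class TrackGroup(BaseModel):
    """An ordered set of managed tracks rendered as one contiguous block."""

    model_config = ConfigDict(frozen=True)

    id: str
    mode: str = "automatic"
    members: tuple[str, ...] = ()  # track-set ids ordered by rank; filled at load
    anchor: Optional[str] = None
    max_visible: Optional[int] = Field(default=None, ge=1)

    @field_validator("mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        if v not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {v!r}")
        return v


class Registry(BaseModel):
    """The validated, fully cross-referenced track registry."""

    model_config = ConfigDict(frozen=True)

    static_tracks: tuple[StaticTrack, ...] = ()
    groups: tuple[TrackGroup, ...] = ()
    track_sets: tuple[TrackSet, ...] = ()
    global_max_visible: Optional[int] = Field(default=None, ge=1)
    base_dir: str = "."  # directory data paths are resolved against

    # -- lookups -----------------------------------------------------------
    def group(self, group_id: str) -> TrackGroup:
        for g in self.groups:
            if g.id == group_id:
                return g
        raise KeyError(group_id)

    def track_set(self, track_id: str) -> TrackSet:
        for t in self.track_sets:
            if t.id == track_id:
                return t
        raise KeyError(track_id)

    def static_track(self, track_id: str) -> StaticTrack:
        for s in self.static_tracks:
            if s.id == track_id:
                return s
        raise KeyError(track_id)

    def resolve_path(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def to_config_text(self) -> str:
        """Serialize back to the configuration dialect (round-trips)."""
        doc: dict = {
            "static_tracks": [
                {"id": s.id, "path": s.path, "position": s.position}
                for s in self.static_tracks
            ],
            "groups": [
                {
                    "id": g.id,
                    "mode": g.mode,
                    **({"anchor": g.anchor} if g.anchor is not None else {}),
                    **(
                        {"max_visible": g.max_visible}
                        if g.max_visible is not None
                        else {}
                    ),
                }
                for g in self.groups
            ],
            "track_sets": [
                {
                    "id": t.id,
                    "signal_path": t.signal_path,
                    "feature_path": t.feature_path,
                    "group_id": t.group_id,
                    "rank": t.rank,
                }
                for t in self.track_sets
            ],
        }
        if self.global_max_visible is not None:
            doc["global_max_visible"] = self.global_max_visible
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _semantic(msg: str) -> ConfigSemanticsError:
    return ConfigSemanticsError(msg)


def load_registry(config_text: str, base_dir: str | Path = ".") -> Registry:
    """Parse and validate a registry configuration document.

    Parameters
    ----------
    config_text:
        JSON text with top-level keys ``static_tracks``, ``groups``,
        ``track_sets`` and optional ``global_max_visible``.
    base_dir:
        Directory against which relative data paths are resolved (defaults to
        the current directory; the CLI passes the configuration file's parent).

    Raises
    ------
    ConfigSyntaxError
        if the text is not valid JSON.
    ConfigSemanticsError
        for duplicate ids, dangling references, anchor cycles or bad caps; the
        message names the offending entity.
    """
    try:
        doc = json.loads(config_text)
    except json.JSONDecodeError as exc:
        raise ConfigSyntaxError(f"configuration is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigSyntaxError("configuration root must be a JSON object")

    try:
        statics = tuple(StaticTrack(**s) for s in doc.get("static_tracks", []))
        raw_groups = [TrackGroup(**g) for g in doc.get("groups", [])]
        track_sets = tuple(TrackSet(**t) for t in doc.get("track_sets", []))
        gmax = doc.get("global_max_visible")
        if gmax is not None and (not isinstance(gmax, int) or gmax < 1):
            raise _semantic(f"global_max_visible must be a positive integer, got {gmax!r}")
    except ConfigSemanticsError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigSemanticsError(str(exc)) from exc

    # id uniqueness across the whole registry
    seen: dict[str, str] = {}
    for kind, ids in (
        ("static track", [s.id for s in statics]),
        ("group", [g.id for g in raw_groups]),
        ("track set", [t.id for t in track_sets]),
    ):
        for i in ids:
            if i in seen:
                raise _semantic(f"duplicate id {i!r} ({seen[i]} vs {kind})")
            seen[i] = kind

    positions = [s.position for s in statics]
    if len(set(positions)) != len(positions):
        dup = next(p for p in positions if positions.count(p) > 1)
        raise _semantic(f"static track position {dup} used more than once")

    group_ids = {g.id for g in raw_groups}
    static_ids = {s.id for s in statics}

    # cross references
    members: dict[str, list[TrackSet]] = {g.id: [] for g in raw_groups}
    for t in track_sets:
        if t.group_id not in group_ids:
            raise _semantic(f"track set {t.id!r} references unknown group {t.group_id!r}")
        members[t.group_id].append(t)
    for gid, ts in members.items():
        if not ts:
            raise _semantic(f"group {gid!r} has no member track sets")
        ranks = [t.rank for t in ts]
        if len(set(ranks)) != len(ranks):
            dup = next(r for r in ranks if ranks.count(r) > 1)
            raise _semantic(f"rank {dup} duplicated within group {gid!r}")

    # anchors: must exist, and the group→group anchor relation must be acyclic
    for g in raw_groups:
        if g.anchor is not None and g.anchor not in static_ids | group_ids:
            raise _semantic(f"group {g.id!r} anchors on unknown target {g.anchor!r}")
    anchor_next = {g.id: g.anchor for g in raw_groups if g.anchor in group_ids}
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(node: str, trail: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = trail[trail.index(node):] + [node]
            raise _semantic("anchor cycle: " + "→".join(cycle))
        state[node] = 0
        nxt = anchor_next.get(node)
        if nxt is not None:
            visit(nxt, trail + [node])
        state[node] = 1

    for gid in anchor_next:
        visit(gid, [])

    groups = tuple(
        g.model_copy(
            update={
                "members": tuple(t.id for t in sorted(members[g.id], key=lambda t: t.rank))
            }
        )
        for g in raw_groups
    )
    return Registry(
        static_tracks=tuple(sorted(statics, key=lambda s: s.position)),
        groups=groups,
        track_sets=track_sets,
        global_max_visible=gmax,
        base_dir=str(base_dir),
    )


def load_registry_file(path: str | Path) -> Registry:
    """Load a registry from a JSON file; relative data paths resolve next to it."""
    path = Path(path)
    return load_registry(path.read_text(), base_dir=path.parent)


# thousands separators tolerated inside coordinates: comma, underscore,
# ordinary space, no-break space (U+00A0) and narrow no-break space (U+202F)
_SEPARATORS = ",_ \u00a0\u202f"
_NUM = "[0-9][0-9" + _SEPARATORS + "]*"
_REGION = re.compile(
    "^(?P<chrom>[^:\\s]+):(?P<start>" + _NUM + ")(?:-|\\.\\.)(?P<end>" + _NUM + ")$"
)


def parse_window(text: str) -> GenomicWindow:
    """Parse ``chrom:start-end`` (or ``chrom:start..end``) into a window.

    Input coordinates follow the genome-browser convention (1-based, inclusive,
    thousands separators allowed, e.g. ``chr2R:8,794,209-8,812,865``); the
    returned window is 0-based half-open.

    Raises
    ------
    RegionSyntaxError
        on malformed text, ``start < 1`` or ``start > end``.
    """
    m = _REGION.match(text.strip())
    if m is None:
        raise RegionSyntaxError(f"cannot parse region {text!r} (expected chrom:start-end)")
    digits = str.maketrans("", "", _SEPARATORS)
    start1 = int(m["start"].translate(digits))
    end1 = int(m["end"].translate(digits))
    if start1 < 1 or start1 > end1:
        raise RegionSyntaxError(f"invalid bounds in region {text!r}: {start1} > {end1}")
    return GenomicWindow(chrom=m["chrom"], start=start1 - 1, end=end1)
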