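"""Track-container composition: classification, ordering, anchoring, caps.

Given a window classification, the engine rebuilds the ordered track container
the way the browser plugin would:

* static tracks keep their configured backbone positions, untouched;
* each ``automatic`` group shows the rank-ordered prefix of its interesting
  tracks, bounded by the group cap and the remaining global budget;
* each group's tracks occupy one contiguous block, placed immediately below
  its anchor (a static track or another group) or appended after the backbone
  when unanchored; blocks anchored on the same target stack in declaration
  order, and anchor chains resolve transitively (they are acyclic by load-time
  validation);
* ``manual`` groups keep their current block; the fresh classification is
  parked in ``pending`` until explicitly applied;
* ``disabled`` groups are ignored entirely and keep their block verbatim;
* overflow flags record truncation so a front-end can show the "data hidden"
  cue.

Composition is a pure function of (registry, classification, previous state):
identical inputs give identical output, and composing twice is idempotent.

Global-budget allocation when the interesting tracks of all groups exceed
``global_max_visible``: groups are processed in container placement order
(anchors resolved, then declaration order); each takes up to
``min(own cap, remaining budget)``; later groups may receive zero slots.
Static tracks never count against the global budget — it exists to bound
automatic additions, not the user's own backbone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import inf
from typing import Optional

from .datamodel import GenomicWindow, Registry, TrackGroup
from .errors import ContractViolationError
from .feature_index import FeatureIndex, query_window

STATE_VERSION = 1

STATIC_ORIGIN = "static"


def group_origin(group_id: str) -> str:
    return f"group:{group_id}"


@dataclass(frozen=True)
class GroupClassification:
    """Rank-ordered partition of one group's members at one window."""

    interesting: tuple[str, ...]
    empty: tuple[str, ...]


@dataclass(frozen=True)
class Classification:
    """Per-group interesting/empty partition for one window.

    Disabled groups are absent from ``per_group``.
    """

    window: GenomicWindow
    per_group: dict[str, GroupClassification]


@dataclass(frozen=True)
class Entry:
    """One container row: a track id plus its origin (static or a group)."""

    track_id: str
    origin: str  # "static" or "group:<id>"


@dataclass
class LayoutState:
    """The ordered track container plus carousel/overflow/pending bookkeeping."""

    container: list[Entry] = field(default_factory=list)
    carousel_offset: dict[str, int] = field(default_factory=dict)
    overflow: dict[str, bool] = field(default_factory=dict)
    pending: dict[str, GroupClassification] = field(default_factory=dict)
    global_overflow: bool = False
    log: list[str] = field(default_factory=list)

    # -- queries -----------------------------------------------------------
    def group_block(self, group_id: str) -> list[str]:
        origin = group_origin(group_id)
        return [e.track_id for e in self.container if e.origin == origin]

    def visible_ids(self) -> list[str]:
        return [e.track_id for e in self.container]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": STATE_VERSION,
            "container": [[e.track_id, e.origin] for e in self.container],
            "carousel_offset": dict(sorted(self.carousel_offset.items())),
            "overflow": dict(sorted(self.overflow.items())),
            "pending": {
                g: {"interesting": list(c.interesting), "empty": list(c.empty)}
                for g, c in sorted(self.pending.items())
            },
            "global_overflow": self.global_overflow,
            "log": list(self.log),
        }

    def to_json(self) -> str:
        """Canonical JSON: UTF-8, sorted keys, no insignificant whitespace."""
        return json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":"), ensure_ascii=False) + "\n"

    @classmethod
    def from_dict(cls, doc: dict) -> "LayoutState":
        if doc.get("version") != STATE_VERSION:
            raise ValueError(f"unsupported state version {doc.get('version')!r}")
        return cls(
            container=[Entry(track_id=t, origin=o) for t, o in doc["container"]],
            carousel_offset={k: int(v) for k, v in doc["carousel_offset"].items()},
            overflow={k: bool(v) for k, v in doc["overflow"].items()},
            pending={
                g: GroupClassification(tuple(c["interesting"]), tuple(c["empty"]))
                for g, c in doc.get("pending", {}).items()
            },
            global_overflow=bool(doc.get("global_overflow", False)),
            log=list(doc.get("log", [])),
        )

    @classmethod
    def from_json(cls, text: str) -> "LayoutState":
        return cls.from_dict(json.loads(text))

    @classmethod
    def initial(cls, registry: Registry) -> "LayoutState":
        """The always-valid starting state: backbone only, offsets zeroed."""
        return cls(
            container=[Entry(s.id, STATIC_ORIGIN) for s in registry.static_tracks],
            carousel_offset={g.id: 0 for g in registry.groups},
            overflow={g.id: False for g in registry.groups},
        )

    # -- invariants --------------------------------------------------------
    def check_invariants(self, registry: Registry) -> None:
        """Raise AssertionError on any violated container invariant."""
        ids = self.visible_ids()
        assert len(ids) == len(set(ids)), "duplicate track ids in container"
        origins = [e.origin for e in self.container]
        for origin in set(origins):
            first = origins.index(origin)
            run = origins[first:first + origins.count(origin)]
            if origin != STATIC_ORIGIN:
                assert all(o == origin for o in run), \
                    f"{origin} entries are not contiguous"
        managed = sum(1 for e in self.container if e.origin != STATIC_ORIGIN)
        if registry.global_max_visible is not None:
            assert managed <= registry.global_max_visible, "global cap exceeded"
        for g in registry.groups:
            block = self.group_block(g.id)
            if g.max_visible is not None:
                assert len(block) <= g.max_visible, f"group {g.id} cap exceeded"
            assert self.carousel_offset.get(g.id, 0) >= 0, "negative carousel offset"


@dataclass(frozen=True)
class GroupSummary:
    n_interesting: int
    n_visible: int
    n_hidden: int


@dataclass(frozen=True)
class LayoutSummary:
    """Per-group and global counts surfaced to the user by the widget."""

    per_group: dict[str, GroupSummary]
    total_visible: int
    any_overflow: bool

    def to_dict(self) -> dict:
        return {
            "version": STATE_VERSION,
            "per_group": {
                g: {
                    "n_interesting": s.n_interesting,
                    "n_visible": s.n_visible,
                    "n_hidden": s.n_hidden,
                }
                for g, s in sorted(self.per_group.items())
            },
            "total_visible": self.total_visible,
            "any_overflow": self.any_overflow,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":"), ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# classification


def classify(registry: Registry, index: FeatureIndex,
             window: GenomicWindow) -> Classification:
    """Partition every non-disabled group into interesting/empty at ``window``.

    Both sub-lists keep the group's rank order.  Disabled groups are omitted.
    """
    hits = query_window(index, window)
    per_group: dict[str, GroupClassification] = {}
    for g in registry.groups:
        if g.mode == "disabled":
            continue
        interesting = tuple(t for t in g.members if t in hits)
        empty = tuple(t for t in g.members if t not in hits)
        per_group[g.id] = GroupClassification(interesting, empty)
    return Classification(window=window, per_group=per_group)


# ---------------------------------------------------------------------------
# placement


def placement_order(registry: Registry) -> list[TrackGroup]:
    """Groups in container placement order: anchor chains resolved depth-first
    below their targets, siblings and unanchored groups in declaration order."""
    static_ids = {s.id for s in registry.static_tracks}
    children: dict[str, list[TrackGroup]] = {}
    roots: list[TrackGroup] = []
    for g in registry.groups:
        if g.anchor is None:
            roots.append(g)
        else:
            children.setdefault(g.anchor, []).append(g)

    ordered: list[TrackGroup] = []

    def walk(g: TrackGroup) -> None:
        ordered.append(g)
        for child in children.get(g.id, []):
            walk(child)

    for s in registry.static_tracks:
        for g in children.get(s.id, []):
            walk(g)
    for g in roots:
        walk(g)
    # groups anchored on a target that is neither a static track nor a group
    # cannot occur after load-time validation, but keep placement total anyway
    placed = {g.id for g in ordered}
    for g in registry.groups:
        if g.id not in placed and g.anchor not in static_ids:
            walk(g)
    return ordered


def _emit_container(registry: Registry,
                    blocks: dict[str, list[str]]) -> tuple[list[Entry], list[str]]:
    """Assemble the container from per-group visible blocks.

    Returns the entry list and diagnostics for anchors that could not be
    resolved (those blocks degrade to end-of-container placement).
    """
    children: dict[str, list[TrackGroup]] = {}
    roots: list[TrackGroup] = []
    static_ids = {s.id for s in registry.static_tracks}
    group_ids = {g.id for g in registry.groups}
    dangling: list[TrackGroup] = []
    for g in registry.groups:
        if g.anchor is None:
            roots.append(g)
        elif g.anchor in static_ids or g.anchor in group_ids:
            children.setdefault(g.anchor, []).append(g)
        else:
            dangling.append(g)

    container: list[Entry] = []
    log: list[str] = []

    def emit_group(g: TrackGroup) -> None:
        origin = group_origin(g.id)
        for tid in blocks.get(g.id, []):
            container.append(Entry(tid, origin))
        for child in children.get(g.id, []):
            emit_group(child)

    for s in registry.static_tracks:
        container.append(Entry(s.id, STATIC_ORIGIN))
        for g in children.get(s.id, []):
            emit_group(g)
    for g in roots:
        emit_group(g)
    for g in dangling:
        log.append(
            f"group {g.id!r}: anchor {g.anchor!r} not present; placed at container end"
        )
        emit_group(g)
    return container, log


# ---------------------------------------------------------------------------
# composition


def compose_layout(registry: Registry, classification: Classification,
                   previous: LayoutState) -> LayoutState:
    """Rebuild the container for a new window classification.

    See the module docstring for the full rule set.  Never raises on anchor
    trouble: unresolvable anchors degrade to end-of-container placement with a
    diagnostic in ``state.log``.
    """
    budget = registry.global_max_visible if registry.global_max_visible is not None else inf

    blocks: dict[str, list[str]] = {}
    overflow: dict[str, bool] = {}
    offsets: dict[str, int] = {}
    pending = dict(previous.pending)
    global_overflow = False

    for g in placement_order(registry):
        if g.mode == "automatic":
            cls_g = classification.per_group.get(g.id)
            interesting = list(cls_g.interesting) if cls_g else []
            cap = g.max_visible if g.max_visible is not None else inf
            quota = int(min(len(interesting), cap, max(0, budget)))
            blocks[g.id] = interesting[:quota]
            budget -= quota
            overflow[g.id] = quota < len(interesting)
            if quota < min(len(interesting), cap):
                global_overflow = True
            offsets[g.id] = 0
            pending.pop(g.id, None)
        else:
            blocks[g.id] = previous.group_block(g.id)
            budget -= len(blocks[g.id])
            offsets[g.id] = previous.carousel_offset.get(g.id, 0)
            if g.mode == "manual":
                cls_g = classification.per_group.get(g.id)
                if cls_g is not None:
                    pending[g.id] = cls_g
                    n_vis = len(set(blocks[g.id]) & set(cls_g.interesting))
                    overflow[g.id] = n_vis < len(cls_g.interesting)
                else:
                    overflow[g.id] = previous.overflow.get(g.id, False)
            else:  # disabled: copied verbatim
                overflow[g.id] = previous.overflow.get(g.id, False)

    container, log = _emit_container(registry, blocks)
    return LayoutState(
        container=container,
        carousel_offset=offsets,
        overflow=overflow,
        pending=pending,
        global_overflow=global_overflow,
        log=log,
    )


def apply_pending(registry: Registry, state: LayoutState,
                  group_id: str) -> LayoutState:
    """Apply a manual group's parked classification to its container block.

    The block is rebuilt exactly as :func:`compose_layout` would build it for
    an automatic group (rank-ordered interesting prefix under the group cap
    and the remaining global budget); the pending entry is cleared; every
    other group is untouched.  Calling it with no pending classification is a
    no-op; calling it on a non-manual group is a contract violation.
    """
    try:
        g = registry.group(group_id)
    except KeyError:
        raise ContractViolationError(f"unknown group {group_id!r}") from None
    if g.mode != "manual":
        raise ContractViolationError(
            f"apply_pending requires a manual group; {group_id!r} is {g.mode}"
        )
    cls_g = state.pending.get(group_id)
    if cls_g is None:
        return state

    others = sum(
        1 for e in state.container
        if e.origin not in (STATIC_ORIGIN, group_origin(group_id))
    )
    budget = inf if registry.global_max_visible is None \
        else registry.global_max_visible - others
    cap = g.max_visible if g.max_visible is not None else inf
    quota = int(min(len(cls_g.interesting), cap, max(0, budget)))

    blocks = {h.id: state.group_block(h.id) for h in registry.groups}
    blocks[group_id] = list(cls_g.interesting[:quota])
    container, log = _emit_container(registry, blocks)

    pending = dict(state.pending)
    del pending[group_id]
    overflow = dict(state.overflow)
    overflow[group_id] = quota < len(cls_g.interesting)
    offsets = dict(state.carousel_offset)
    offsets[group_id] = 0
    return replace(
        state,
        container=container,
        carousel_offset=offsets,
        overflow=overflow,
        pending=pending,
        log=state.log + log,
    )


def summarize(classification: Classification, state: LayoutState) -> LayoutSummary:
    """Per-group interesting/visible/hidden counts plus global totals.

    ``n_visible`` counts visible tracks that are interesting at the current
    window, so ``n_visible + n_hidden == n_interesting`` holds in every mode
    (a manual group's stale block may display tracks that are no longer
    interesting; those do not count as visible-interesting).
    """
    per_group: dict[str, GroupSummary] = {}
    for gid, cls_g in classification.per_group.items():
        visible = set(state.group_block(gid))
        n_int = len(cls_g.interesting)
        n_vis = len(visible & set(cls_g.interesting))
        per_group[gid] = GroupSummary(
            n_interesting=n_int, n_visible=n_vis, n_hidden=n_int - n_vis
        )
    return LayoutSummary(
        per_group=per_group,
        total_visible=len(state.container),
        any_overflow=bool(state.global_overflow or any(state.overflow.values())),
    )
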