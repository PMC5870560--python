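"""Carousel browsing: cyclic rotation through a group's interesting tracks.

When a group's interesting tracks exceed its visible quota, only a prefix is
displayed and the rest stay hidden.  The carousel lets the user scroll through
all of them without lifting the cap: each rotation advances the viewing
window by ``ceil(V/2)`` positions on the ring of N interesting tracks (V =
visible slots), so half of the visible tracks are swapped for hidden ones in
the predefined rank order, with wrap-around — "infinite scrolling".

``ceil`` rather than ``floor`` guarantees progress even at V = 1.  The window
slides forward (the later half of the previous view is retained), so repeated
clicks read downward through the predefined order.  After
``N / gcd(N, ceil(V/2))`` rotations the view first returns to its start.
"""
from __future__ import annotations

from dataclasses import replace
from math import ceil, gcd

from .datamodel import Registry
from .errors import ContractViolationError
from .layout_engine import Classification, LayoutState, _emit_container


def rotation_step(visible: int) -> int:
    """Number of tracks replaced per rotation: ``ceil(V/2)``."""
    return ceil(visible / 2)


def cyclic_window(ring: list[str], offset: int, size: int) -> list[str]:
    """``size`` consecutive ring elements starting at ``offset`` (wrapping)."""
    n = len(ring)
    if n <= size:
        return list(ring)
    return [ring[(offset + i) % n] for i in range(size)]


def rotate(state: LayoutState, registry: Registry,
           classification: Classification, group_id: str) -> LayoutState:
    """Advance a group's carousel by one click.

    With N interesting tracks and V visible slots: a no-op when ``N <= V``
    (nothing is hidden); otherwise the offset advances by ``ceil(V/2)`` modulo
    N and the group's container block is rewritten to the new cyclic window.
    All other groups and all static tracks are untouched; the overflow flag
    stays set, since tracks remain hidden at every offset.
    """
    try:
        registry.group(group_id)
    except KeyError:
        raise ContractViolationError(f"unknown group {group_id!r}") from None
    cls_g = classification.per_group.get(group_id)
    if cls_g is None:
        raise ContractViolationError(
            f"group {group_id!r} is not classified at the current window"
        )
    ring = list(cls_g.interesting)
    visible = state.group_block(group_id)
    n, v = len(ring), len(visible)
    if n <= v:
        return state

    offset = (state.carousel_offset.get(group_id, 0) + rotation_step(v)) % n
    blocks = {g.id: state.group_block(g.id) for g in registry.groups}
    blocks[group_id] = cyclic_window(ring, offset, v)
    container, log = _emit_container(registry, blocks)
    offsets = dict(state.carousel_offset)
    offsets[group_id] = offset
    return replace(state, container=container, carousel_offset=offsets,
                   log=state.log + log)


def rotation_cycle_length(n: int, v: int) -> int:
    """Rotations until the visible window first returns to its start.

    Equals ``N / gcd(N, ceil(V/2))``.  Requires ``N > V >= 1`` — with every
    interesting track already visible there is no carousel to cycle.
    """
    if not (isinstance(n, int) and isinstance(v, int) and n > v >= 1):
        raise ContractViolationError(
            f"rotation_cycle_length requires N > V >= 1, got N={n}, V={v}"
        )
    return n // gcd(n, rotation_step(v))
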