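"""Static rendering of a composed layout: the verification surrogate for the
browser's track container.

One horizontal panel per container entry, top to bottom in container order.
Track-set panels draw the bedGraph signal as a filled step area with the
companion features as boxes underneath; static-track panels draw their
features as boxes.  A shared coordinate axis sits at the bottom, and a group
with hidden interesting tracks gets an overflow glyph (a marker whose SVG id
``overflow-cue-<group>`` is string-searchable).  SVG output is deterministic
for identical inputs.
"""
from __future__ import annotations

import zlib
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .datamodel import GenomicWindow, Registry
from .feature_index import read_features
from .layout_engine import STATIC_ORIGIN, LayoutState
from .signal import read_signal

PANEL_GID_PREFIX = "panel-"
OVERFLOW_GID_PREFIX = "overflow-cue-"

_PALETTE = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _feature_boxes(ax, path: Path, window: GenomicWindow, y0: float,
                   height: float, color: str) -> None:
    for f in read_features(path):
        if f.chrom == window.chrom and f.start < window.end and f.end > window.start:
            start = max(f.start, window.start)
            end = min(f.end, window.end)
            ax.add_patch(Rectangle((start, y0), end - start, height,
                                   facecolor=color, edgecolor="none"))


def render_view(registry: Registry, state: LayoutState, window: GenomicWindow,
                out: str | Path) -> Path:
    """Render the container to an SVG or PNG file (by extension of ``out``).

    Raises ``OSError`` naming the track when a referenced data file is
    missing.
    """
    out = Path(out)
    entries = state.container
    n = len(entries)
    fig_h = 0.9 * max(n, 1) + 0.8
    with plt.rc_context({"svg.hashsalt": "dynatrack"}):
        fig, axes = plt.subplots(
            max(n, 1), 1, sharex=True, figsize=(8, fig_h), squeeze=False,
        )
        axes = axes[:, 0]
        overflow_marked: set[str] = set()
        for ax, entry in zip(axes, entries):
            ax.set_gid(f"{PANEL_GID_PREFIX}{entry.track_id}")
            ax.set_yticks([])
            ax.set_ylabel(entry.track_id, rotation=0, ha="right", va="center",
                          fontsize=8)
            color = _PALETTE[zlib.crc32(entry.origin.encode()) % len(_PALETTE)]
            try:
                if entry.origin == STATIC_ORIGIN:
                    track = registry.static_track(entry.track_id)
                    _feature_boxes(ax, registry.resolve_path(track.path),
                                   window, 0.2, 0.6, "0.3")
                    ax.set_ylim(0, 1)
                else:
                    ts = registry.track_set(entry.track_id)
                    rows = read_signal(registry.resolve_path(ts.signal_path), window)
                    top = max((v for _, _, v in rows), default=1.0) or 1.0
                    for s, e, v in rows:
                        ax.fill_between([s, e], [v, v], step="post",
                                        color=color, alpha=0.8)
                    _feature_boxes(ax, registry.resolve_path(ts.feature_path),
                                   window, -0.18 * top, 0.12 * top, "0.4")
                    ax.set_ylim(-0.2 * top, 1.05 * top)
            except OSError as exc:
                plt.close(fig)
                raise OSError(f"track {entry.track_id!r}: {exc}") from exc
            gid = entry.origin.removeprefix("group:")
            if (entry.origin != STATIC_ORIGIN
                    and state.overflow.get(gid, False)
                    and gid not in overflow_marked):
                glyph = ax.annotate("...more", xy=(0.99, 0.75),
                                    xycoords="axes fraction", ha="right",
                                    fontsize=7, color="crimson")
                glyph.set_gid(f"{OVERFLOW_GID_PREFIX}{gid}")
                overflow_marked.add(gid)
        if n == 0:
            axes[0].set_yticks([])
        axes[-1].set_xlim(window.start, window.end)
        axes[-1].set_xlabel(f"{window.chrom} position (bp)")
        axes[-1].ticklabel_format(axis="x", style="plain", useOffset=False)
        fig.suptitle(str(window), fontsize=9)
        fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
        plt.close(fig)
    return out
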