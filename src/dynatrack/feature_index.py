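"""Compiled interval index over all companion feature datasets.

Every track set registered in the engine contributes its companion features
(the regions of significant signal) to one aggregate index.  For a genomic
window the index answers "which tracks have at least one feature overlapping
this window" — the *locus-specific interesting* tracks; all other managed
tracks are *locus-specific empty* at that window.

Interestingness is purely presence-based: one overlapping base pair suffices.
No score threshold and no minimum-overlap fraction are applied, and strand is
ignored; separating signal from background is the job of whatever upstream
pipeline produced the feature files.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Optional

from intervaltree import IntervalTree

from .datamodel import GenomicWindow, Registry
from .errors import FeatureFormatError

Format = Literal["bed", "gff3", "auto"]


@dataclass(frozen=True)
class Feature:
    """A half-open interval ``[start, end)`` owned by a track set."""

    chrom: str
    start: int
    end: int
    track_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"feature requires start < end, got [{self.start}, {self.end})")


def _sniff_format(path: Path) -> Format:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".bed"):
        return "bed"
    if name.endswith((".gff", ".gff3")):
        return "gff3"
    raise FeatureFormatError(
        f"cannot infer feature format from extension of {path.name!r}; pass format explicitly"
    )


def _open_text(path: Path) -> IO[str]:
    if path.name.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_coords(raw_start: str, raw_end: str, lineno: int, path: Path,
                  one_based: bool) -> tuple[int, int]:
    try:
        start, end = int(raw_start), int(raw_end)
    except ValueError as exc:
        raise FeatureFormatError(
            f"{path}:{lineno}: non-integer coordinates {raw_start!r}/{raw_end!r}"
        ) from exc
    if one_based:
        start -= 1
    if start < 0 or start >= end:
        raise FeatureFormatError(
            f"{path}:{lineno}: invalid interval [{start}, {end}) after conversion"
        )
    return start, end


def read_features(path: str | Path, format: Format = "auto",
                  track_id: Optional[str] = None) -> list[Feature]:
    """Read a BED (0-based half-open) or GFF3 (1-based inclusive) feature file.

    ``format="auto"`` dispatches on the file extension (``.bed[.gz]`` /
    ``.gff[3][.gz]``).  Comment (``#``), ``track`` and ``browser`` lines and
    blank lines are skipped.  Only chromosome and coordinates are consumed;
    strand, score and attributes are ignored.  GFF3 coordinates are converted
    to half-open; a GFF3 row whose converted interval is empty is rejected.

    Raises :class:`FeatureFormatError` citing the line number for malformed
    rows, ``OSError`` for unreadable files.
    """
    path = Path(path)
    fmt = _sniff_format(path) if format == "auto" else format
    feats: list[Feature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if fmt == "bed":
                if len(cols) < 3:
                    raise FeatureFormatError(f"{path}:{lineno}: BED row has < 3 columns")
                chrom, raw_s, raw_e = cols[0], cols[1], cols[2]
                start, end = _parse_coords(raw_s, raw_e, lineno, path, one_based=False)
            else:  # gff3
                if len(cols) < 5:
                    raise FeatureFormatError(f"{path}:{lineno}: GFF3 row has < 5 columns")
                chrom, raw_s, raw_e = cols[0], cols[3], cols[4]
                start, end = _parse_coords(raw_s, raw_e, lineno, path, one_based=True)
            if not chrom:
                raise FeatureFormatError(f"{path}:{lineno}: empty chromosome name")
            feats.append(Feature(chrom=chrom, start=start, end=end, track_id=track_id))
    return feats


@dataclass
class FeatureIndex:
    """Per-chromosome interval trees mapping intervals to owning track ids.

    ``track_universe`` also retains tracks whose feature file is empty: they
    are indexed, simply never interesting.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    track_universe: set[str] = field(default_factory=set)

    def add(self, feature: Feature) -> None:
        if feature.track_id is None:
            raise ValueError("indexed features must carry a track_id")
        tree = self.trees.setdefault(feature.chrom, IntervalTree())
        tree.addi(feature.start, feature.end, feature.track_id)
        self.track_universe.add(feature.track_id)

    def register_track(self, track_id: str) -> None:
        """Add a track to the universe even if it contributes no features."""
        self.track_universe.add(track_id)


def build_index(registry: Registry) -> FeatureIndex:
    """Compile every track set's companion features into one queryable index.

    Construction is deterministic and query results are equivalent to a linear
    scan over all features.  Read errors are re-raised prefixed with the
    offending track id.
    """
    index = FeatureIndex()
    for ts in registry.track_sets:
        index.register_track(ts.id)
        try:
            feats = read_features(registry.resolve_path(ts.feature_path),
                                  track_id=ts.id)
        except (FeatureFormatError, OSError) as exc:
            raise type(exc)(f"track set {ts.id!r}: {exc}") from exc
        for f in feats:
            index.add(f)
    return index


def query_window(index: FeatureIndex, window: GenomicWindow) -> set[str]:
    """Track ids with >= 1 feature overlapping ``window`` (half-open overlap).

    A feature ``[s, e)`` overlaps iff ``s < window.end and e > window.start``
    on the same chromosome; abutting intervals do not overlap.  Unknown
    chromosomes yield the empty set.
    """
    tree = index.trees.get(window.chrom)
    if tree is None:
        return set()
    return {iv.data for iv in tree.overlap(window.start, window.end)}


def scan_window(features: Iterable[Feature], window: GenomicWindow) -> set[str]:
    """Linear-scan reference for :func:`query_window` (used by diagnostics)."""
    return {
        f.track_id
        for f in features
        if f.track_id is not None
        and f.chrom == window.chrom
        and f.start < window.end
        and f.end > window.start
    }


def index_to_dict(index: FeatureIndex) -> dict:
    """JSON-serializable form of an index (sorted, canonical ordering)."""
    return {
        "version": 1,
        "track_universe": sorted(index.track_universe),
        "features": sorted(
            [chrom, iv.begin, iv.end, iv.data]
            for chrom, tree in index.trees.items()
            for iv in tree
        ),
    }


def index_from_dict(doc: dict) -> FeatureIndex:
    index = FeatureIndex()
    for tid in doc.get("track_universe", []):
        index.register_track(tid)
    for chrom, start, end, tid in doc.get("features", []):
        index.add(Feature(chrom=chrom, start=start, end=end, track_id=tid))
    return index
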