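"""Quantitative signal reading for rendering: bedGraph (primary) and bigWig.

bedGraph is the required, plain-text path; bigWig files (``.bw`` /
``.bigwig``) are read through pyBigWig behind the same contract when that
library is importable.
"""
from __future__ import annotations

import gzip
from pathlib import Path

from .datamodel import GenomicWindow
from .errors import FeatureFormatError

SignalRows = list[tuple[int, int, float]]  # (start, end, value), half-open


def read_signal(path: str | Path, window: GenomicWindow) -> SignalRows:
    """Signal rectangles overlapping ``window``, clipped to its bounds.

    Returns ``(start, end, value)`` rows sorted by start; regions without a
    row are zero by convention.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".bw", ".bigwig")):
        return _read_bigwig(path, window)
    return _read_bedgraph(path, window)


def _read_bedgraph(path: Path, window: GenomicWindow) -> SignalRows:
    opener = gzip.open if path.name.endswith(".gz") else open
    rows: SignalRows = []
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FeatureFormatError(f"{path}:{lineno}: bedGraph row has < 4 columns")
            chrom, raw_s, raw_e, raw_v = cols[:4]
            if chrom != window.chrom:
                continue
            try:
                start, end, value = int(raw_s), int(raw_e), float(raw_v)
            except ValueError as exc:
                raise FeatureFormatError(f"{path}:{lineno}: malformed bedGraph row") from exc
            if start < window.end and end > window.start:
                rows.append((max(start, window.start), min(end, window.end), value))
    rows.sort()
    return rows


def _read_bigwig(path: Path, window: GenomicWindow) -> SignalRows:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise FeatureFormatError(
            f"{path}: bigWig support requires pyBigWig"
        ) from exc
    rows: SignalRows = []
    bw = pyBigWig.open(str(path))
    try:
        if window.chrom in (bw.chroms() or {}):
            for start, end, value in bw.intervals(window.chrom, window.start,
                                                  window.end) or []:
                rows.append((max(start, window.start), min(end, window.end),
                             float(value)))
    finally:
        bw.close()
    rows.sort()
    return rows
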