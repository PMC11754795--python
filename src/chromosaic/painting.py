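"""In silico chromosome ancestry painting from diagnostic-tag hits.

Tag hits are binned into fixed, half-open windows along each chromosome;
each window is assigned the dominant group's label when the evidence passes
a minimum-hit and dominance-ratio rule, and NA otherwise (NA marks regions
in which no origin could be attributed — distinct from any real "unknown"
ancestor group, which carries its own tags and ordinary label). Maximal
same-label runs of windows are merged into ancestry segments, the painting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import tags as tags_mod
from .seqio import BedRecord
from .tags import DiagnosticTag, TagConfig, TagHit

NA_LABEL = "NA"


@dataclass(frozen=True)
class PaintingConfig:
    """Window size (bp), minimum hits to call a window, dominance ratio
    (winning group's share of the window's hits), and optional per-group
    normalization by tag-set size for unbalanced panels."""

    window: int = 10_000
    min_hits: int = 5
    ratio: float = 0.75
    normalize_by_tag_count: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError(f"window must be positive, got {self.window}")
        if not (0.5 < self.ratio <= 1.0):
            raise ValueError(f"dominance ratio must be in (0.5, 1], got {self.ratio}")
        if self.min_hits < 0:
            raise ValueError(f"min_hits must be >= 0, got {self.min_hits}")


@dataclass(frozen=True)
class PaintingWindow:
    chrom: str
    start: int
    end: int
    counts: Mapping[str, int]
    label: str = NA_LABEL

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_window_hits(
    hits: Sequence[TagHit],
    chrom_lengths: Mapping[str, int],
    cfg: PaintingConfig | None = None,
    groups: Sequence[str] | None = None,
) -> list[PaintingWindow]:
    """Bin hits by start coordinate into tiling windows (last may be short).

    Every chromosome in ``chrom_lengths`` is tiled even if hitless; counts
    are kept for every group in ``groups`` (inferred from hits if omitted).
    """
    cfg = cfg or PaintingConfig()
    group_list = sorted(groups) if groups is not None else sorted({h.group for h in hits})
    per_window: dict[tuple[str, int], dict[str, int]] = {}
    for h in hits:
        if h.chrom not in chrom_lengths:
            raise KeyError(f"hit on unknown chromosome {h.chrom!r}")
        if h.start >= chrom_lengths[h.chrom]:
            raise ValueError(f"hit at {h.chrom}:{h.start} beyond chromosome end")
        key = (h.chrom, h.start // cfg.window)
        per_window.setdefault(key, {}).setdefault(h.group, 0)
        per_window[key][h.group] += 1

    windows: list[PaintingWindow] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_win = max(1, -(-length // cfg.window))
        for w in range(n_win):
            start = w * cfg.window
            end = min(start + cfg.window, length)
            counts = per_window.get((chrom, w), {})
            windows.append(
                PaintingWindow(chrom, start, end, {g: counts.get(g, 0) for g in group_list})
            )
    return windows


def assign_ancestry(
    counts: Mapping[str, int | float], cfg: PaintingConfig | None = None
) -> str:
    """Dominance rule: argmax group iff total >= min_hits and the winner
    holds at least ``ratio`` of all hits; NA otherwise, ties NA."""
    cfg = cfg or PaintingConfig()
    total = sum(counts.values())
    if total < cfg.min_hits or total == 0:
        return NA_LABEL
    best = max(counts.values())
    winners = [g for g, c in counts.items() if c == best]
    if len(winners) != 1:
        return NA_LABEL
    if best / total < cfg.ratio:
        return NA_LABEL
    return winners[0]


def label_windows(
    windows: Iterable[PaintingWindow],
    cfg: PaintingConfig | None = None,
    tag_counts: Mapping[str, int] | None = None,
) -> list[PaintingWindow]:
    """Apply the dominance rule per window; with
    ``cfg.normalize_by_tag_count`` counts are first divided by each group's
    total tag count (min_hits still applies to raw totals)."""
    cfg = cfg or PaintingConfig()
    out = []
    for w in windows:
        counts: Mapping[str, int | float] = w.counts
        if cfg.normalize_by_tag_count:
            if tag_counts is None:
                raise ValueError("normalize_by_tag_count requires tag_counts")
            if sum(w.counts.values()) < cfg.min_hits:
                out.append(PaintingWindow(w.chrom, w.start, w.end, w.counts, NA_LABEL))
                continue
            counts = {g: c / tag_counts[g] for g, c in w.counts.items() if tag_counts.get(g)}
            scaled_cfg = PaintingConfig(cfg.window, 0, cfg.ratio)
            label = assign_ancestry(counts, scaled_cfg)
        else:
            label = assign_ancestry(counts, cfg)
        out.append(PaintingWindow(w.chrom, w.start, w.end, w.counts, label))
    return out


@dataclass(frozen=True)
class AncestrySegment:
    chrom: str
    start: int
    end: int
    label: str
    n_windows: int

    def as_bed(self) -> BedRecord:
        return BedRecord(self.chrom, self.start, self.end, self.label)


def merge_segments(windows: Sequence[PaintingWindow]) -> list[AncestrySegment]:
    """Merge maximal runs of equal-label adjacent windows per chromosome."""
    segments: list[AncestrySegment] = []
    prev: PaintingWindow | None = None
    for w in windows:
        if prev is not None and w.chrom == prev.chrom and w.start < prev.end:
            raise ValueError("windows must be sorted and non-overlapping")
        if (
            segments
            and prev is not None
            and w.chrom == segments[-1].chrom
            and w.start == segments[-1].end
            and w.label == segments[-1].label
        ):
            last = segments[-1]
            segments[-1] = AncestrySegment(
                last.chrom, last.start, w.end, last.label, last.n_windows + 1
            )
        else:
            segments.append(AncestrySegment(w.chrom, w.start, w.end, w.label, 1))
        prev = w
    return segments


@dataclass(frozen=True)
class Painting:
    """Full painting of an assembly: labelled windows, merged segments and
    per-label base fractions (labels are groups plus NA; fractions sum
    to 1)."""

    windows: tuple[PaintingWindow, ...]
    segments: tuple[AncestrySegment, ...]
    fractions: Mapping[str, float]

    def to_bed(self) -> list[BedRecord]:
        return [s.as_bed() for s in self.segments]

    def window_table(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            row = {"chrom": w.chrom, "start": w.start, "end": w.end, "label": w.label}
            row.update(w.counts)
            rows.append(row)
        return pd.DataFrame(rows)


def paint_windows(
    hits: Sequence[TagHit],
    chrom_lengths: Mapping[str, int],
    cfg: PaintingConfig | None = None,
    groups: Sequence[str] | None = None,
    tag_counts: Mapping[str, int] | None = None,
) -> Painting:
    cfg = cfg or PaintingConfig()
    windows = label_windows(count_window_hits(hits, chrom_lengths, cfg, groups), cfg, tag_counts)
    segments = merge_segments(windows)
    total = sum(chrom_lengths.values())
    fractions: dict[str, float] = {}
    labels = set(groups or ()) | {NA_LABEL} | {s.label for s in segments}
    for label in sorted(labels):
        covered = sum(s.end - s.start for s in segments if s.label == label)
        fractions[label] = covered / total
    return Painting(tuple(windows), tuple(segments), fractions)


def paint_assembly(
    assembly: Mapping[str, str],
    tags: Sequence[DiagnosticTag],
    cfg: PaintingConfig | None = None,
    tag_cfg: TagConfig | None = None,
) -> Painting:
    """match_tags -> count_window_hits -> assign_ancestry -> merge_segments.

    Returns the painting with per-group genome fractions (the Fig.-6-style
    ancestral contribution estimate when run per chromosome set).
    """
    cfg = cfg or PaintingConfig()
    if tags and tag_cfg is None:
        tag_cfg = TagConfig(k=len(tags[0].sequence))
    hits = tags_mod.match_tags(assembly, tags, tag_cfg) if tags else []
    chrom_lengths = {c: len(s) for c, s in assembly.items()}
    groups = sorted({t.group for t in tags})
    tag_counts: dict[str, int] = {}
    for t in tags:
        tag_counts[t.group] = tag_counts.get(t.group, 0) + 1
    return paint_windows(hits, chrom_lengths, cfg, groups, tag_counts or None)


def accuracy_vs_truth(painting: Painting, truth_segments: Sequence[BedRecord]) -> float:
    """Fraction of truth-covered bases whose painted label matches the truth
    label (NA counts as a miss)."""
    matched = 0
    total = 0
    for t in truth_segments:
        total += t.end - t.start
        for s in painting.segments:
            if s.chrom != t.chrom or s.label != t.label:
                continue
            lo, hi = max(s.start, t.start), min(s.end, t.end)
            if hi > lo:
                matched += hi - lo
    return matched / total if total else 0.0
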