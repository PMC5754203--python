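"""Transcription start site cluster (TSC) calling and quantification.

A TSC groups neighboring single-base transcription start sites into one
promoter call.  The input is a stranded per-base map of 5'-end tag counts
(one :class:`TagTrack` per library); clusters are called on the track pooled
over the whole time course, then quantified per time point.

Coordinates are 0-based half-open throughout.  Strands are processed
independently: no bidirectional-promoter merging is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TagTrack",
    "TSC",
    "pool_tracks",
    "call_tscs",
    "main_tss",
    "quantify",
    "assign_to_genes",
    "filter_blacklist",
]


class TagTrack:
    """Stranded per-base 5'-end tag counts for one contig of one library.

    Parameters
    ----------
    species, contig, strand
        Identity of the track; ``strand`` is ``'+'`` or ``'-'``.
    counts
        Mapping of 0-based position to a nonnegative integer tag count, or a
        pair of parallel arrays ``(positions, values)``.
    library_size
        Total mapped tags in the library this track came from.  Must be at
        least the sum of ``counts`` (the track may cover one contig of a
        larger library).  If omitted, it defaults to the track total.
    time_point
        Hour index of the library within a time series, or ``None`` for a
        pooled track.
    """

    __slots__ = ("species", "contig", "strand", "positions", "values",
                 "library_size", "time_point")

    def __init__(self, species: str, contig: str, strand: str,
                 counts: Mapping[int, int] | tuple | None = None,
                 library_size: int | None = None,
                 time_point: int | None = None):
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if counts is None:
            pos = np.empty(0, dtype=np.int64)
            val = np.empty(0, dtype=np.int64)
        elif isinstance(counts, tuple):
            pos = np.asarray(counts[0], dtype=np.int64)
            val = np.asarray(counts[1], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            pos, val = pos[order], val[order]
        else:
            pos = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
            val = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
            order = np.argsort(pos, kind="stable")
            pos, val = pos[order], val[order]
        if np.any(val < 0):
            raise ValueError("tag counts must be nonnegative")
        keep = val > 0
        pos, val = pos[keep], val[keep]
        if pos.size > 1 and np.any(np.diff(pos) == 0):
            raise ValueError("duplicate positions in tag track")
        self.species = species
        self.contig = contig
        self.strand = strand
        self.positions = pos
        self.values = val
        total = int(val.sum())
        if library_size is None:
            library_size = total
        if library_size < total:
            raise ValueError("library_size smaller than summed track counts")
        self.library_size = int(library_size)
        self.time_point = time_point

    # -- basic queries -----------------------------------------------------

    def total(self) -> int:
        """Summed tag count over the whole track."""
        return int(self.values.sum())

    def count_in(self, start: int, end: int) -> int:
        """Tags in the half-open interval ``[start, end)``."""
        i = np.searchsorted(self.positions, start, side="left")
        j = np.searchsorted(self.positions, end, side="left")
        return int(self.values[i:j].sum())

    def counts_dict(self) -> dict[int, int]:
        return dict(zip(self.positions.tolist(), self.values.tolist()))

    def translated(self, offset: int) -> "TagTrack":
        """A copy of the track with every position shifted by ``offset``."""
        return TagTrack(self.species, self.contig, self.strand,
                        (self.positions + offset, self.values.copy()),
                        library_size=self.library_size,
                        time_point=self.time_point)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"TagTrack({self.species}:{self.contig}{self.strand} "
                f"t={self.time_point} n_pos={self.positions.size} "
                f"total={self.total()})")


def pool_tracks(tracks: Sequence[TagTrack]) -> TagTrack:
    """Sum a set of same-contig, same-strand tracks (e.g. over time points)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.species, t.contig, t.strand) != (first.species, first.contig,
                                               first.strand):
            raise ValueError("cannot pool tracks from different contigs/strands")
    pos = np.concatenate([t.positions for t in tracks])
    val = np.concatenate([t.values for t in tracks])
    upos, inv = np.unique(pos, return_inverse=True)
    uval = np.zeros(upos.size, dtype=np.int64)
    np.add.at(uval, inv, val)
    return TagTrack(first.species, first.contig, first.strand, (upos, uval),
                    library_size=sum(t.library_size for t in tracks),
                    time_point=None)


@dataclass
class TSC:
    """One promoter call: an interval of clustered TSS positions.

    ``start <= main_tss < end``; ``counts``/``rpm`` are per-time-point masked
    arrays filled in by :func:`quantify` (masked entries mark missing
    libraries, not zeros).
    """

    id: str
    species: str
    contig: str
    strand: str
    start: int
    end: int
    main_tss: int | None
    pooled_count: int
    counts: np.ma.MaskedArray | None = None
    rpm: np.ma.MaskedArray | None = None
    gene_id: str | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("TSC interval must be non-empty")
        if self.main_tss is not None and not (self.start <= self.main_tss < self.end):
            raise ValueError("main_tss must lie inside the TSC interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def main_tss(tsc: TSC, pooled_track: TagTrack) -> int:
    """Most heavily used position of a TSC on the pooled track.

    Ties are broken toward the 5'-most position on the TSC's strand
    (smallest coordinate on '+', largest on '-').
    """
    i = np.searchsorted(pooled_track.positions, tsc.start, side="left")
    j = np.searchsorted(pooled_track.positions, tsc.end, side="left")
    pos = pooled_track.positions[i:j]
    val = pooled_track.values[i:j]
    if pos.size == 0 or val.sum() == 0:
        raise ValueError(f"TSC {tsc.id} has no tags in pooled track")
    best = val == val.max()
    cand = pos[best]
    return int(cand.min() if tsc.strand == "+" else cand.max())


def call_tscs(pooled_track: TagTrack, min_pos_count: int = 2,
              max_gap: int = 50, min_total: int = 15) -> list[TSC]:
    """Call TSCs on a pooled (time-summed) tag track.

    Positions with at least ``min_pos_count`` tags anchor clusters; anchor
    runs separated by at most ``max_gap`` intervening bases are merged; the
    resulting interval is kept when the total tag count inside it (including
    sub-threshold positions) reaches ``min_total``.  Returned TSCs are
    non-overlapping on the strand and sorted by coordinate.
    """
    anchors = pooled_track.positions[pooled_track.values >= min_pos_count]
    if anchors.size == 0:
        return []
    # gap between consecutive anchors = intervening bases
    breaks = np.flatnonzero(np.diff(anchors) - 1 > max_gap) + 1
    starts = anchors[np.concatenate(([0], breaks))]
    ends = anchors[np.concatenate((breaks - 1, [anchors.size - 1]))] + 1
    out: list[TSC] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        pooled = pooled_track.count_in(s, e)
        if pooled < min_total:
            continue
        tsc = TSC(id=f"{pooled_track.species}:{pooled_track.contig}:{s}-{e}:{pooled_track.strand}",
                  species=pooled_track.species, contig=pooled_track.contig,
                  strand=pooled_track.strand, start=s, end=e,
                  main_tss=None, pooled_count=pooled)
        tsc.main_tss = main_tss(tsc, pooled_track)
        out.append(tsc)
    return out


def quantify(tsc: TSC, tracks: Sequence[TagTrack | None],
             n_time_points: int | None = None) -> TSC:
    """Fill per-time-point counts and RPM for a TSC.

    ``tracks`` is indexed by time point; a ``None`` entry (missing library)
    yields a masked value, not a zero.  RPM divides by that library's own
    size.  The TSC is modified in place and returned.
    """
    T = n_time_points if n_time_points is not None else len(tracks)
    counts = np.ma.masked_all(T, dtype=float)
    rpm = np.ma.masked_all(T, dtype=float)
    for t, track in enumerate(tracks):
        if track is None:
            continue
        if track.contig != tsc.contig or track.strand != tsc.strand:
            raise ValueError("track does not cover the TSC's contig/strand")
        c = track.count_in(tsc.start, tsc.end)
        counts[t] = c
        if track.library_size > 0:
            rpm[t] = c / track.library_size * 1e6
        else:
            rpm[t] = 0.0
    tsc.counts = counts
    tsc.rpm = rpm
    return tsc


@dataclass(frozen=True)
class Transcript:
    """Minimal annotated transcript: its 5' end is what TSC matching uses."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    five_prime: int  # 0-based position of the annotated transcript 5' end


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance in bp from a base to a half-open interval (0 if inside)."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def assign_to_genes(tscs: Sequence[TSC], transcripts: Sequence[Transcript],
                    match_dist: int = 150) -> dict[str, str | None]:
    """Attribute TSCs to genes via annotated transcript 5' ends.

    A transcript matches a TSC when its 5' end lies within ``match_dist`` bp
    of the TSC interval on the same strand; the TSC inherits the gene of the
    nearest matching 5' end.  Equidistant conflicts between genes are broken
    lexicographically on gene id (and logged).  Unmatched TSCs are orphans
    (``gene_id`` stays ``None``).
    """
    by_key: dict[tuple[str, str], list[Transcript]] = {}
    for tr in transcripts:
        by_key.setdefault((tr.contig, tr.strand), []).append(tr)
    assignments: dict[str, str | None] = {}
    for tsc in tscs:
        cands = []
        for tr in by_key.get((tsc.contig, tsc.strand), ()):
            d = _interval_distance(tr.five_prime, tsc.start, tsc.end)
            if d <= match_dist:
                cands.append((d, tr.gene_id))
        if not cands:
            tsc.gene_id = None
            assignments[tsc.id] = None
            continue
        cands.sort()
        best_d = cands[0][0]
        best_genes = sorted({g for d, g in cands if d == best_d})
        if len(best_genes) > 1:
            logger.info("TSC %s: equidistant gene conflict %s; keeping %s",
                        tsc.id, best_genes, best_genes[0])
        tsc.gene_id = best_genes[0]
        assignments[tsc.id] = best_genes[0]
    return assignments


def filter_blacklist(tscs: Iterable[TSC],
                     blacklist: Sequence[tuple[str, int, int]]) -> list[TSC]:
    """Drop TSCs overlapping any blacklist interval by >= 1 bp.

    ``blacklist`` holds ``(contig, start, end)`` half-open intervals (e.g.
    rDNA repeats or heterochromatic regions).  Strand is ignored: a repeat
    masks both strands.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in blacklist:
        by_contig.setdefault(contig, []).append((s, e))
    out = []
    for tsc in tscs:
        hit = any(tsc.overlaps(s, e) for s, e in by_contig.get(tsc.contig, ()))
        if not hit:
            out.append(tsc)
    return out
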