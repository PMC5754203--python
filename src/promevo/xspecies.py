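"""Cross-species projection, syntenic filtering and functional conservation.

The multi-genome alignment is abstracted as pairwise :class:`AlignmentMap`
objects from one reference frame to each target species.  Each map is a set
of colinear blocks carrying a per-base status on the reference:

* ``orthologous`` (O): the base aligns to a target base,
* ``alignment_gap`` (G): the base falls in an alignment gap (no target base),
* ``assembly_gap`` (A): the target assembly has no sequence there,
* positions outside any block are ``unaligned`` (U).

Within a block, the k-th orthologous reference base maps to the k-th target
base (reversed on the '-' strand), so the number of O bases equals the target
span.  This representation carries the assembly-gap/alignment-gap distinction
that the syntenic filter needs and that chain files cannot encode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tsc import TSC, TagTrack, call_tscs

logger = logging.getLogger(__name__)

# per-base status codes on the reference
STATUS_ORTH = 0      # 'O'
STATUS_ALNGAP = 1    # 'G'
STATUS_ASMGAP = 2    # 'A'
STATUS_UNALIGNED = 3 # 'U' (outside all blocks)

STATUS_CHARS = np.array(["O", "G", "A", "U"])
CHAR_TO_STATUS = {"O": STATUS_ORTH, "G": STATUS_ALNGAP,
                  "A": STATUS_ASMGAP, "U": STATUS_UNALIGNED}

__all__ = [
    "MapBlock", "AlignmentMap", "ScoreTrack",
    "syntenic_filter", "project_interval", "conservation_call",
    "ConservationCall", "subclade_conservation", "build_character_matrix",
    "harmonize_pair", "conservation_metaprofile", "selection_fractions",
    "quantile_correlation",
]


@dataclass
class MapBlock:
    """One colinear alignment block with per-reference-base status."""

    ref_contig: str
    ref_start: int
    ref_end: int
    target_contig: str
    target_start: int
    target_end: int
    target_strand: str
    status: np.ndarray  # uint8 codes, length ref_end - ref_start

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.uint8)
        if self.status.size != self.ref_end - self.ref_start:
            raise ValueError("status array length must equal reference span")
        n_orth = int((self.status == STATUS_ORTH).sum())
        if n_orth != self.target_end - self.target_start:
            raise ValueError(
                "orthologous base count must equal target span "
                f"({n_orth} != {self.target_end - self.target_start})")
        if self.target_strand not in ("+", "-"):
            raise ValueError("target_strand must be '+' or '-'")


class AlignmentMap:
    """Pairwise coordinate projection from a reference to a target species."""

    def __init__(self, ref_species: str, target_species: str,
                 blocks: list[MapBlock]):
        self.ref_species = ref_species
        self.target_species = target_species
        self.blocks = sorted(blocks, key=lambda b: (b.ref_contig, b.ref_start))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[MapBlock]]] = {}
        by_contig: dict[str, list[MapBlock]] = {}
        for b in self.blocks:
            by_contig.setdefault(b.ref_contig, []).append(b)
        for contig, bl in by_contig.items():
            starts = np.array([b.ref_start for b in bl])
            ends = np.array([b.ref_end for b in bl])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping blocks on reference {contig}")
            self._index[contig] = (starts, ends, bl)
        # prefix counts of orthologous bases inside each block
        self._orth_cum = {id(b): np.concatenate(
            ([0], np.cumsum(b.status == STATUS_ORTH))) for b in self.blocks}

    # -- lookups -----------------------------------------------------------

    def block_at(self, contig: str, pos: int) -> MapBlock | None:
        entry = self._index.get(contig)
        if entry is None:
            return None
        starts, ends, bl = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return bl[i]
        return None

    def status(self, contig: str, start: int, end: int) -> np.ndarray:
        """Per-base status codes over ``[start, end)`` (U outside blocks)."""
        out = np.full(end - start, STATUS_UNALIGNED, dtype=np.uint8)
        entry = self._index.get(contig)
        if entry is None:
            return out
        for b in entry[2]:
            lo, hi = max(start, b.ref_start), min(end, b.ref_end)
            if lo < hi:
                out[lo - start:hi - start] = b.status[lo - b.ref_start:hi - b.ref_start]
        return out

    def project_base(self, contig: str, pos: int):
        """Project one base; ``None`` unless its status is orthologous.

        Returns ``(target_contig, target_pos, target_strand)``.
        """
        b = self.block_at(contig, pos)
        if b is None:
            return None
        off = pos - b.ref_start
        if b.status[off] != STATUS_ORTH:
            return None
        k = int(self._orth_cum[id(b)][off])
        if b.target_strand == "+":
            tpos = b.target_start + k
        else:
            tpos = b.target_end - 1 - k
        return (b.target_contig, tpos, b.target_strand)

    def invert(self) -> "AlignmentMap":
        """Map from target to reference, defined on orthologous bases only."""
        inv_blocks: list[MapBlock] = []
        for b in self.blocks:
            orth = b.status == STATUS_ORTH
            if not orth.any():
                continue
            # contiguous runs of orthologous bases map to contiguous target runs
            idx = np.flatnonzero(orth)
            run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
            run_starts = idx[np.concatenate(([0], run_breaks))]
            run_ends = idx[np.concatenate((run_breaks - 1, [idx.size - 1]))] + 1
            cum = self._orth_cum[id(b)]
            for rs, re in zip(run_starts.tolist(), run_ends.tolist()):
                n = re - rs
                k0 = int(cum[rs])
                if b.target_strand == "+":
                    ts, te = b.target_start + k0, b.target_start + k0 + n
                else:
                    te = b.target_end - k0
                    ts = te - n
                inv_blocks.append(MapBlock(
                    ref_contig=b.target_contig, ref_start=ts, ref_end=te,
                    target_contig=b.ref_contig,
                    target_start=b.ref_start + rs, target_end=b.ref_start + re,
                    target_strand=b.target_strand,
                    status=np.zeros(n, dtype=np.uint8)))
        return AlignmentMap(self.target_species, self.ref_species, inv_blocks)


def identity_map(ref_species: str, target_species: str,
                 contig_lengths: dict[str, int]) -> AlignmentMap:
    """An all-orthologous identity map (useful for a species onto itself)."""
    blocks = [MapBlock(c, 0, n, c, 0, n, "+", np.zeros(n, dtype=np.uint8))
              for c, n in contig_lengths.items()]
    return AlignmentMap(ref_species, target_species, blocks)


# ---------------------------------------------------------------------------
# syntenic filter and interval projection


def syntenic_filter(tsc: TSC, amap: AlignmentMap, window: int = 800,
                    min_frac_aligned: float = 0.5,
                    min_frac_orth: float = 0.25) -> bool:
    """Decide whether a TSC has a unique syntenic alignment in the target.

    A window of ``window`` bp centered on the TSC midpoint must satisfy:
    (i) both window endpoints fall in alignment blocks of the same target
    contig and strand (an endpoint inside an assembly gap does not map);
    (ii) at least ``min_frac_aligned`` of window bases are aligned, i.e.
    neither assembly gaps nor unaligned; (iii) at least ``min_frac_orth``
    of window bases are orthologous.
    """
    mid = tsc.midpoint
    ws = mid - window // 2
    we = ws + window
    ends = []
    for pos in (ws, we - 1):
        b = amap.block_at(tsc.contig, pos)
        if b is None or b.status[pos - b.ref_start] == STATUS_ASMGAP:
            return False
        ends.append((b.target_contig, b.target_strand))
    if ends[0] != ends[1]:
        return False
    st = amap.status(tsc.contig, max(ws, 0), we)
    if ws < 0:  # window off contig start: missing bases count as unaligned
        st = np.concatenate([np.full(-ws, STATUS_UNALIGNED, np.uint8), st])
    frac_aligned = np.mean((st == STATUS_ORTH) | (st == STATUS_ALNGAP))
    frac_orth = np.mean(st == STATUS_ORTH)
    return bool(frac_aligned >= min_frac_aligned and frac_orth >= min_frac_orth)


def project_interval(contig: str, start: int, end: int, amap: AlignmentMap):
    """Smallest target interval covering projections of orthologous bases.

    Returns ``(target_contig, target_start, target_end, target_strand)`` or
    ``None`` when no base projects (or projections span several target
    contigs/strands, which cannot form a single interval).
    """
    entry = amap._index.get(contig)
    if entry is None:
        return None
    lo = hi = None
    key = None
    for b in entry[2]:
        s, e = max(start, b.ref_start), min(end, b.ref_end)
        if s >= e:
            continue
        seg = b.status[s - b.ref_start:e - b.ref_start]
        orth = np.flatnonzero(seg == STATUS_ORTH)
        if orth.size == 0:
            continue
        cum = amap._orth_cum[id(b)]
        k_first = int(cum[s - b.ref_start + orth[0]])
        k_last = int(cum[s - b.ref_start + orth[-1]])
        if b.target_strand == "+":
            tlo = b.target_start + k_first
            thi = b.target_start + k_last + 1
        else:
            thi = b.target_end - k_first
            tlo = b.target_end - 1 - k_last
        if key is None:
            key = (b.target_contig, b.target_strand)
            lo, hi = tlo, thi
        elif key != (b.target_contig, b.target_strand):
            return None
        else:
            lo, hi = min(lo, tlo), max(hi, thi)
    if key is None:
        return None
    return (key[0], lo, hi, key[1])


# ---------------------------------------------------------------------------
# functional conservation


@dataclass
class ConservationCall:
    """Functional-conservation verdict for one reference TSC in one target."""

    tsc_id: str
    target_species: str
    status: str  # 'present' | 'absent' | 'not_alignable'
    ref_signal: float | None = None
    target_signal: float | None = None


def conservation_call(ref_tags: float, target_tags: float, fold: float = 100,
                      low_ref: float = 100, min_ref: float = 15) -> str:
    """Call a promoter present or absent in a target species from tag counts.

    With at least ``low_ref`` reference tags, the promoter is absent when the
    target signal is at least ``fold``-fold lower (boundary inclusive).
    Weakly expressed reference promoters (fewer than ``low_ref`` tags) are
    only called absent when the target shows no signal at all.  Promoters
    under ``min_ref`` tags must be excluded upstream.
    """
    if ref_tags < min_ref:
        raise ValueError(
            f"reference signal {ref_tags} below the {min_ref}-tag eligibility "
            "filter; exclude such promoters before calling conservation")
    if ref_tags >= low_ref:
        return "absent" if target_tags <= ref_tags / fold else "present"
    return "absent" if target_tags == 0 else "present"


def subclade_conservation(tsc_ids: list[str],
                          calls: dict[tuple[str, str], str],
                          subclades: dict[str, list[str]]) -> pd.DataFrame:
    """Fraction of reference TSCs functionally conserved in nested subclades.

    ``calls[(tsc_id, species)]`` holds 'present'/'absent'/'not_alignable'.
    For every subclade both reporting conventions are returned: the fraction
    of all eligible TSCs conserved in every member (non-alignable counting
    as unconserved) and the fraction among alignable TSCs only.
    """
    rows = []
    for name, members in subclades.items():
        n_total = len(tsc_ids)
        n_align = n_cons = 0
        for tid in tsc_ids:
            st = [calls.get((tid, sp), "not_alignable") for sp in members]
            if all(s != "not_alignable" for s in st):
                n_align += 1
                if all(s == "present" for s in st):
                    n_cons += 1
        rows.append({
            "subclade": name, "n_total": n_total, "n_alignable": n_align,
            "n_conserved": n_cons,
            "frac_of_all": n_cons / n_total if n_total else np.nan,
            "frac_of_alignable": n_cons / n_align if n_align else np.nan,
        })
    return pd.DataFrame(rows).set_index("subclade")


# ---------------------------------------------------------------------------
# non-redundant cross-species peak set


def build_character_matrix(tsc_sets: dict[str, list[TSC]],
                           maps: dict[str, AlignmentMap],
                           ref_species: str | None = None):
    """Collapse all species' TSCs in a common frame into binary characters.

    ``maps[species]`` projects the reference frame onto that species (the
    reference needs no map).  Projected TSCs overlapping by >= 1 bp on the
    same strand collapse into one character; a taxon's state is 1 when it
    contributed a TSC to the group, '?' when the group's region is not
    alignable to that taxon, else 0.

    Returns a :class:`promevo.phylo.CharacterMatrix`.
    """
    from .phylo import CharacterMatrix

    taxa = sorted(tsc_sets)
    if ref_species is None:
        ref_species = taxa[0]
    inverse = {sp: m.invert() for sp, m in maps.items() if sp != ref_species}

    # project every TSC into the reference frame
    projected = []  # (contig, start, end, strand, taxon)
    unplaced = []   # taxon-private TSCs that cannot reach the reference frame
    for sp in taxa:
        for tsc in tsc_sets[sp]:
            if sp == ref_species:
                projected.append((tsc.contig, tsc.start, tsc.end, tsc.strand, sp))
                continue
            inv = inverse.get(sp)
            proj = (project_interval(tsc.contig, tsc.start, tsc.end, inv)
                    if inv is not None else None)
            if proj is None:
                unplaced.append(sp)
                continue
            tcontig, ts, te, tstrand = proj
            strand = tsc.strand if tstrand == "+" else ("-" if tsc.strand == "+" else "+")
            projected.append((tcontig, ts, te, strand, sp))

    # sweep-merge overlapping projected intervals per (contig, strand)
    groups: list[tuple[str, int, int, str, set]] = []
    projected.sort(key=lambda r: (r[0], r[3], r[1]))
    for contig, s, e, strand, sp in projected:
        if groups and groups[-1][0] == contig and groups[-1][3] == strand \
                and s < groups[-1][2]:
            gc, gs, ge, gst, members = groups[-1]
            groups[-1] = (gc, gs, max(ge, e), gst, members | {sp})
        else:
            groups.append((contig, s, e, strand, {sp}))

    n_chars = len(groups) + len(unplaced)
    states = np.zeros((len(taxa), n_chars), dtype=np.int8)
    for j, (contig, s, e, strand, members) in enumerate(groups):
        for i, sp in enumerate(taxa):
            if sp in members:
                states[i, j] = 1
            elif sp == ref_species:
                states[i, j] = 0
            else:
                amap = maps.get(sp)
                ok = amap is not None and \
                    project_interval(contig, s, e, amap) is not None
                states[i, j] = 0 if ok else -1
    for k, sp in enumerate(unplaced):
        j = len(groups) + k
        states[:, j] = -1
        states[taxa.index(sp), j] = 1
    intervals = [(c, s, e, st) for c, s, e, st, _ in groups]
    return CharacterMatrix(taxa=taxa, states=states, metadata=intervals)


# ---------------------------------------------------------------------------
# cross-species harmonization


def harmonize_pair(ref_tscs: list[TSC], target_tscs: list[TSC],
                   target_pooled: dict[tuple[str, str], TagTrack],
                   amap: AlignmentMap, min_tags: int = 10,
                   syntenic_kwargs: dict | None = None
                   ) -> tuple[list[TSC], list[tuple[str, str]]]:
    """Rescue uncalled orthologous promoters and reconcile gene assignments.

    For every reference TSC whose orthologous target window carries at least
    ``min_tags`` pooled tags but overlaps no called target TSC, a rescued
    TSC is added to the target set.  When a conserved TSC is gene-assigned
    on one side only, the assignment is copied to the other (returned as
    ``(tsc_id, gene_id)`` update pairs for the reference side).

    ``target_pooled`` maps ``(contig, strand)`` to the pooled target track.
    """
    skw = syntenic_kwargs or {}
    augmented = list(target_tscs)
    ref_updates: list[tuple[str, str]] = []
    for rtsc in ref_tscs:
        if not syntenic_filter(rtsc, amap, **skw):
            continue
        proj = project_interval(rtsc.contig, rtsc.start, rtsc.end, amap)
        if proj is None:
            continue
        tcontig, ts, te, tstrand = proj
        strand = rtsc.strand if tstrand == "+" else ("-" if rtsc.strand == "+" else "+")
        overlapping = [t for t in augmented
                       if t.contig == tcontig and t.strand == strand
                       and t.overlaps(ts, te)]
        if overlapping:
            tgt = overlapping[0]
            if rtsc.gene_id is not None and tgt.gene_id is None:
                tgt.gene_id = rtsc.gene_id
            elif tgt.gene_id is not None and rtsc.gene_id is None:
                ref_updates.append((rtsc.id, tgt.gene_id))
            continue
        track = target_pooled.get((tcontig, strand))
        if track is None:
            continue
        tags = track.count_in(ts, te)
        if tags < min_tags:
            continue
        rescued = call_tscs(
            TagTrack(track.species, tcontig, strand,
                     (track.positions[(track.positions >= ts) & (track.positions < te)],
                      track.values[(track.positions >= ts) & (track.positions < te)]),
                     library_size=track.library_size),
            min_pos_count=1, max_gap=te - ts, min_total=min_tags)
        if rescued:
            r = rescued[0]
            r.labels["rescued"] = True
            r.gene_id = rtsc.gene_id
            augmented.append(r)
    return augmented, ref_updates


# ---------------------------------------------------------------------------
# sequence-conservation summaries from score tracks


@dataclass
class ScoreTrack:
    """Per-base real-valued conservation scores for a set of contigs.

    ``kind`` is 'phastcons' (probability-like, in [0, 1]) or 'phylop'
    (signed rate-based).  ``data`` maps contig to ``(start, values)``;
    positions outside the stored arrays read as NaN.
    """

    kind: str
    data: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("phastcons", "phylop"):
            raise ValueError("kind must be 'phastcons' or 'phylop'")
        for contig, (start, vals) in self.data.items():
            vals = np.asarray(vals, dtype=float)
            if self.kind == "phastcons":
                finite = vals[np.isfinite(vals)]
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise ValueError("phastcons-like scores must lie in [0, 1]")
            self.data[contig] = (start, vals)

    def values(self, contig: str, start: int, end: int) -> np.ndarray:
        out = np.full(end - start, np.nan)
        entry = self.data.get(contig)
        if entry is None:
            return out
        s0, vals = entry
        lo, hi = max(start, s0), min(end, s0 + vals.size)
        if lo < hi:
            out[lo - start:hi - start] = vals[lo - s0:hi - s0]
        return out


def _oriented_window(tsc: TSC, track: ScoreTrack, flank: int) -> np.ndarray:
    """Scores over main TSS +/- flank, oriented 5'->3' on the TSC strand."""
    v = track.values(tsc.contig, tsc.main_tss - flank, tsc.main_tss + flank + 1)
    return v if tsc.strand == "+" else v[::-1]


def conservation_metaprofile(tscs: list[TSC], track: ScoreTrack,
                             flank: int = 500, n_boot: int = 100,
                             seed: int = 0):
    """Median per-base conservation profile around main TSSs.

    Returns ``(median, se)`` vectors of length ``2*flank + 1``; ``se`` is the
    bootstrap standard error of the median (``None`` when ``n_boot == 0``).
    Windows are strand-oriented so negative offsets are upstream.
    """
    if not tscs:
        raise ValueError("no promoters given")
    mat = np.vstack([_oriented_window(t, track, flank) for t in tscs])
    med = np.nanmedian(mat, axis=0)
    if n_boot <= 0:
        return med, None
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, mat.shape[0], mat.shape[0])
        boots[b] = np.nanmedian(mat[idx], axis=0)
    return med, boots.std(axis=0, ddof=1)


def selection_fractions(tscs: list[TSC], phylop: ScoreTrack,
                        subregions: dict[str, tuple[int, int]],
                        thresh: float = 0.1) -> pd.DataFrame:
    """Fractions of promoter-subregion bases under purifying/positive selection.

    Subregions are half-open offset ranges relative to the main TSS (strand-
    oriented).  Purifying: phyloP > ``thresh``; positive (faster than
    neutral): phyloP < ``-thresh``.
    """
    rows = []
    for name, (a, b) in subregions.items():
        vals = []
        for t in tscs:
            w = _oriented_window(t, phylop, max(abs(a), abs(b)))
            center = max(abs(a), abs(b))
            vals.append(w[center + a:center + b])
        v = np.concatenate(vals)
        v = v[np.isfinite(v)]
        rows.append({"subregion": name, "n_bases": v.size,
                     "frac_purifying": float(np.mean(v > thresh)) if v.size else np.nan,
                     "frac_positive": float(np.mean(v < -thresh)) if v.size else np.nan})
    return pd.DataFrame(rows).set_index("subregion")


# default subregion bands around the main TSS (bp offsets, half-open);
# the upstream band is the documented -300..-50 region, the motif bands
# bracket the canonical TATA/Inr/DPE positions and are configurable.
DEFAULT_SUBREGIONS: dict[str, tuple[int, int]] = {
    "Upstream": (-300, -50),
    "TATA": (-40, -20),
    "Inr": (-10, 10),
    "DPE": (20, 40),
    "Downstream": (50, 150),
}


def quantile_correlation(profile_conservation: dict[str, float],
                         tscs: list[TSC], track: ScoreTrack,
                         subregions: dict[str, tuple[int, int]] | None = None,
                         n_quantiles: int = 10) -> pd.DataFrame:
    """Correlate expression-profile conservation with sequence conservation.

    The Pearson correlation (and its test) is computed on unbinned per-TSC
    values: profile conservation vs. the mean score over each subregion.
    Quantile binning of the score distributions is provided for reporting
    only (column ``quantile_scores``: list of per-bin arrays).
    """
    if subregions is None:
        subregions = DEFAULT_SUBREGIONS
    tscs = [t for t in tscs if t.id in profile_conservation]
    if len(tscs) < 3:
        raise ValueError("need at least 3 promoters with both measures")
    cons = np.array([profile_conservation[t.id] for t in tscs])
    rows = []
    for name, (a, b) in subregions.items():
        flank = max(abs(a), abs(b))
        means = np.array([np.nanmean(_oriented_window(t, track, flank)
                                     [flank + a:flank + b]) for t in tscs])
        ok = np.isfinite(means) & np.isfinite(cons)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 promoters with scores in {name}")
        r, p = stats.pearsonr(cons[ok], means[ok])
        q = pd.qcut(cons[ok], min(n_quantiles, ok.sum()), labels=False,
                    duplicates="drop")
        qscores = [means[ok][q == k] for k in range(int(q.max()) + 1)]
        rows.append({"subregion": name, "n": int(ok.sum()),
                     "pearson_r": r, "p_value": p, "quantile_scores": qscores})
    return pd.DataFrame(rows).set_index("subregion")
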