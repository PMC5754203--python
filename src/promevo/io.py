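"""File formats: bedGraph, BED6/TSV, alignment-map TSV, PHYLIP, newick, GTF.

Dialect notes
-------------
* bedGraph values are integer tag counts; 0-based half-open intervals; the
  strand is carried in the filename suffix (``.plus.bedGraph`` /
  ``.minus.bedGraph``), one file per strand per time point.
* The alignment-map TSV has columns ``ref_contig ref_start ref_end
  target_species target_contig target_start target_end target_strand
  status_rle`` where the last column run-length encodes the per-base status
  (``O`` orthologous, ``G`` alignment gap, ``A`` assembly gap), e.g.
  ``400O10A390O``.  Chain files cannot carry the assembly-gap vs
  alignment-gap distinction the syntenic filter needs, hence this dialect.
* Newick output carries no branch lengths (parsimony topologies only).

Parsing raises :class:`FormatError` with the offending line number.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import CharacterMatrix, Tree, tree_from_nested
from .tsc import TSC, TagTrack, Transcript
from .xspecies import CHAR_TO_STATUS, STATUS_CHARS, AlignmentMap, MapBlock

__all__ = ["FormatError", "write_bedgraph", "read_bedgraph",
           "bedgraph_name", "write_tscs_bed", "read_tscs_bed",
           "write_tscs_tsv", "write_alignment_map", "read_alignment_map",
           "write_newick", "read_newick", "write_fasta", "read_fasta",
           "write_gtf", "read_gtf_transcripts", "write_warp_path"]


class FormatError(ValueError):
    """Malformed input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# bedGraph


def bedgraph_name(species: str, time_point: int | None, strand: str) -> str:
    suffix = "plus" if strand == "+" else "minus"
    tp = "pooled" if time_point is None else f"t{time_point:02d}"
    return f"{species}.{tp}.{suffix}.bedGraph"


def write_bedgraph(track: TagTrack, path) -> None:
    with open(path, "w") as fh:
        for pos, val in zip(track.positions.tolist(), track.values.tolist()):
            fh.write(f"{track.contig}\t{pos}\t{pos + 1}\t{val}\n")


def read_bedgraph(path, species: str, strand: str,
                  library_size: int | None = None,
                  time_point: int | None = None) -> dict[str, TagTrack]:
    """Read a single-strand bedGraph into per-contig tag tracks."""
    per_contig: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(path, lineno, "expected 4 columns")
            try:
                contig, start, end, val = parts[0], int(parts[1]), \
                    int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from None
            if end <= start:
                raise FormatError(path, lineno, "empty interval")
            pos, cnt = per_contig.setdefault(contig, ([], []))
            for p in range(start, end):
                pos.append(p)
                cnt.append(val)
    return {c: TagTrack(species, c, strand, (np.array(p), np.array(v)),
                        library_size=library_size, time_point=time_point)
            for c, (p, v) in per_contig.items()}


# ---------------------------------------------------------------------------
# TSC BED6 / extended TSV


def write_tscs_bed(tscs: list[TSC], path) -> None:
    """BED6: name is the TSC id, score the pooled tag count."""
    with open(path, "w") as fh:
        for t in sorted(tscs, key=lambda x: (x.contig, x.start)):
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.id}\t"
                     f"{t.pooled_count}\t{t.strand}\n")


def read_tscs_bed(path, species: str) -> list[TSC]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(path, lineno, "expected 6 BED columns")
            try:
                contig, start, end, name, score, strand = parts
                out.append(TSC(id=name, species=species, contig=contig,
                               strand=strand, start=int(start), end=int(end),
                               main_tss=None, pooled_count=int(score)))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from None
    return out


def write_tscs_tsv(tscs: list[TSC], path) -> None:
    """Extended table: BED6 fields plus main TSS, gene and per-time-point RPM."""
    rows = []
    for t in tscs:
        row = {"contig": t.contig, "start": t.start, "end": t.end,
               "id": t.id, "pooled_count": t.pooled_count, "strand": t.strand,
               "main_tss": t.main_tss, "gene_id": t.gene_id or ""}
        if t.rpm is not None:
            for k, v in enumerate(np.ma.filled(t.rpm, np.nan)):
                row[f"rpm_{k:02d}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment maps

_RLE_RE = re.compile(r"(\d+)([OGA])")


def _rle_encode(status: np.ndarray) -> str:
    chars = STATUS_CHARS[status]
    out = []
    i = 0
    while i < len(chars):
        j = i
        while j < len(chars) and chars[j] == chars[i]:
            j += 1
        out.append(f"{j - i}{chars[i]}")
        i = j
    return "".join(out)


def _rle_decode(text: str, path, lineno: int) -> np.ndarray:
    pieces = []
    pos = 0
    for m in _RLE_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(path, lineno, f"bad status RLE {text!r}")
        pieces.append(np.full(int(m.group(1)), CHAR_TO_STATUS[m.group(2)],
                              dtype=np.uint8))
        pos = m.end()
    if pos != len(text):
        raise FormatError(path, lineno, f"bad status RLE {text!r}")
    return np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)


MAP_COLUMNS = ["ref_contig", "ref_start", "ref_end", "target_species",
               "target_contig", "target_start", "target_end",
               "target_strand", "status_rle"]


def write_alignment_map(amap: AlignmentMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref_species=" + amap.ref_species + "\n")
        fh.write("\t".join(MAP_COLUMNS) + "\n")
        for b in amap.blocks:
            fh.write("\t".join(map(str, [
                b.ref_contig, b.ref_start, b.ref_end, amap.target_species,
                b.target_contig, b.target_start, b.target_end,
                b.target_strand, _rle_encode(b.status)])) + "\n")


def read_alignment_map(path, ref_species: str | None = None) -> AlignmentMap:
    blocks = []
    target_species = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#ref_species="):
                ref_species = line.split("=", 1)[1]
                continue
            if line.startswith(("#", "ref_contig")):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(path, lineno, "expected 9 columns")
            try:
                block = MapBlock(
                    ref_contig=parts[0], ref_start=int(parts[1]),
                    ref_end=int(parts[2]), target_contig=parts[4],
                    target_start=int(parts[5]), target_end=int(parts[6]),
                    target_strand=parts[7],
                    status=_rle_decode(parts[8], path, lineno))
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from None
            target_species = parts[3]
            blocks.append(block)
    if target_species is None:
        raise FormatError(path, 0, "no alignment blocks found")
    return AlignmentMap(ref_species or "ref", target_species, blocks)


# ---------------------------------------------------------------------------
# trees


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def _skip_branch_length(text: str, j: int) -> int:
    if j < len(text) and text[j] == ":":  # tolerate and ignore lengths
        m = re.match(r":[0-9.eE+-]+", text[j:])
        if m:
            j += m.end()
    return j


def _parse_newick_node(text: str, i: int, path):
    """Recursive-descent parse of the newick topology dialect."""
    if text[i] == "(":
        children = []
        i += 1
        while True:
            child, i = _parse_newick_node(text, i, path)
            children.append(child)
            if text[i] == ",":
                i += 1
                continue
            if text[i] == ")":
                i = _skip_branch_length(text, i + 1)
                break
            raise FormatError(path, 1, f"unexpected character {text[i]!r}")
        # fold multifurcations (the unrooted top node) into nested pairs
        node = children[0]
        for c in children[1:]:
            node = (node, c)
        return node, i
    m = re.match(r"[^(),;:]+", text[i:])
    if not m:
        raise FormatError(path, 1, f"expected a label at position {i}")
    label = m.group(0)
    return label, _skip_branch_length(text, i + m.end())


def read_newick(source) -> Tree:
    """Parse a newick topology (branch lengths tolerated and ignored)."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text, path = Path(source).read_text(), source
    else:
        text, path = str(source), "<string>"
    text = text.strip()
    if not text.endswith(";"):
        raise FormatError(path, 1, "newick string must end with ';'")
    nested, i = _parse_newick_node(text[:-1] + ";", 0, path)
    return tree_from_nested(nested)


def write_phylip(matrix: CharacterMatrix, path) -> None:
    Path(path).write_text(matrix.to_phylip())


def read_phylip(path) -> CharacterMatrix:
    return CharacterMatrix.from_phylip(Path(path).read_text())


# ---------------------------------------------------------------------------
# FASTA (via biopython)


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=contig, description="")
               for contig, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF (transcripts only; enough to carry annotated 5' ends)


def write_gtf(transcripts: list[Transcript], path,
              transcript_length: int = 500) -> None:
    with open(path, "w") as fh:
        for tr in transcripts:
            if tr.strand == "+":
                start, end = tr.five_prime + 1, tr.five_prime + transcript_length
            else:
                start, end = tr.five_prime - transcript_length + 2, tr.five_prime + 1
            attrs = (f'gene_id "{tr.gene_id}"; '
                     f'transcript_id "{tr.transcript_id}";')
            fh.write(f"{tr.contig}\tpromevo\ttranscript\t{max(start, 1)}\t"
                     f"{end}\t.\t{tr.strand}\t.\t{attrs}\n")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path) -> list[Transcript]:
    """Extract transcripts (gene id + annotated 5' end) from a GTF file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(path, lineno, "expected 9 GTF columns")
            if parts[2] != "transcript":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(path, lineno, "missing gene/transcript id")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from None
            strand = parts[6]
            five_prime = start - 1 if strand == "+" else end - 1
            out.append(Transcript(attrs["gene_id"], attrs["transcript_id"],
                                  parts[0], strand, five_prime))
    return out


# ---------------------------------------------------------------------------
# warp paths


def write_warp_path(path_obj, path) -> None:
    """Two-column TSV of matched hours (reference, target)."""
    ha = path_obj.hours_a[path_obj.pairs[:, 0]]
    hb = path_obj.hours_b[path_obj.pairs[:, 1]]
    pd.DataFrame({"ref_hour": ha, "target_hour": hb}).to_csv(
        path, sep="\t", index=False)
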