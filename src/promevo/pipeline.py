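"""End-to-end pipeline driver over a synthetic clade.

Runs the stages in dependency order — simulate, call, quantify, assign,
conserve, matrix, tree, warp, classify, entropy, motifs — and stamps every
output with the configuration hash and seed so any artifact is regenerable
from config + seed alone.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .classify import (classify_hk_dev, cluster_profiles,
                       profile_conservation, shannon_entropy)
from .config import RunConfig
from .motifs import core_promoter_pwms, enrichment, qda_phase_classifier, \
    scan_promoters
from .phylo import best_tree
from .synth import CladeSpec, simulate_clade
from .tsc import assign_to_genes, call_tscs, filter_blacklist, quantify
from .warp import apply_warp, distance_matrix, dtw_align, preprocess, Profile
from .xspecies import (build_character_matrix, conservation_call,
                       project_interval, subclade_conservation,
                       syntenic_filter)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed or its prerequisites are missing."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _nested_subclades(tree, ref: str) -> dict[str, list[str]]:
    """Subclades of increasing size containing the reference species."""
    from .synth import _tree_leaves

    path = []

    def find(node):
        if isinstance(node, str):
            return node == ref
        for child in node:
            if find(child):
                path.append(node)
                return True
        return False

    find(tree)
    out = {}
    for node in path:
        leaves = sorted(_tree_leaves(node))
        if len(leaves) >= 2:
            out["+".join(leaves)] = leaves
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic-clade analysis; returns stage results.

    Outputs are written under ``out_dir`` (defaults to ``config.out_dir``);
    ``provenance.json`` records the config hash and seed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- simulate --------------------------------------------------------
    spec = CladeSpec(n_tscs=config.n_tscs, depth=config.depth,
                     time_points=config.time_points, seed=config.seed)
    clade = simulate_clade(spec)
    ref = clade.ref_species
    results["clade"] = clade
    T = spec.time_points

    # ---- call + quantify + assign ---------------------------------------
    tsc_sets: dict[str, list] = {}
    for sp in spec.taxa:
        tscs = []
        for strand in ("+", "-"):
            tscs.extend(call_tscs(clade.pooled[sp][strand],
                                  min_pos_count=config.min_pos_count,
                                  max_gap=config.max_gap,
                                  min_total=config.min_total))
        tscs = filter_blacklist(tscs, config.blacklist)
        for t in tscs:
            tracks = [clade.tracks[sp][tp][t.strand] for tp in range(T)]
            quantify(t, tracks)
        assign_to_genes(tscs, clade.transcripts, match_dist=config.tss_match)
        tsc_sets[sp] = sorted(tscs, key=lambda x: (x.contig, x.start))
        pio.write_tscs_bed(tsc_sets[sp], out / f"{sp}.tscs.bed")
        pio.write_tscs_tsv(tsc_sets[sp], out / f"{sp}.tscs.tsv")
    results["tscs"] = tsc_sets

    # ---- conservation ----------------------------------------------------
    ref_tscs = [t for t in tsc_sets[ref] if t.pooled_count >= config.min_tags]
    if not ref_tscs:
        raise PipelineError("conserve", "no eligible reference TSCs (>= "
                            f"{config.min_tags} tags)")
    calls: dict[tuple[str, str], str] = {}
    for t in ref_tscs:  # the reference trivially carries its own promoters
        calls[(t.id, ref)] = "present"
    for sp in spec.taxa[1:]:
        amap = clade.maps[sp]
        pooled_sp = clade.pooled[sp]
        for t in ref_tscs:
            if not syntenic_filter(t, amap, window=config.synteny_window,
                                   min_frac_aligned=config.frac_aligned,
                                   min_frac_orth=config.frac_orth):
                calls[(t.id, sp)] = "not_alignable"
                continue
            proj = project_interval(t.contig, t.start, t.end, amap)
            if proj is None:
                calls[(t.id, sp)] = "not_alignable"
                continue
            tc, ts, te, tstrand = proj
            strand = t.strand if tstrand == "+" else ("-" if t.strand == "+" else "+")
            tags = pooled_sp[strand].count_in(ts, te) if tc == "chr1" else 0
            calls[(t.id, sp)] = conservation_call(
                t.pooled_count, tags, fold=config.fold,
                low_ref=config.low_ref, min_ref=config.min_tags)
    subclades = _nested_subclades(spec.tree, ref)
    cons = subclade_conservation([t.id for t in ref_tscs], calls, subclades)
    cons.to_csv(out / "subclade_conservation.tsv", sep="\t")
    results["conservation"] = cons
    results["calls"] = calls

    # ---- character matrix + tree ----------------------------------------
    matrix = build_character_matrix(tsc_sets, clade.maps, ref_species=ref)
    (out / "characters.phy").write_text(matrix.to_phylip())
    trees, length = best_tree(matrix)
    pio.write_newick(trees[0], out / "species_tree.nwk")
    results["tree"] = trees[0]
    results["tree_length"] = length
    results["matrix"] = matrix

    # ---- time-series registration ---------------------------------------
    # gene-level profiles (summed TSC RPM per gene) drive the global paths
    def gene_matrix(sp):
        per_gene: dict[str, np.ndarray] = {}
        for t in tsc_sets[sp]:
            if t.gene_id is None or t.rpm is None:
                continue
            per_gene.setdefault(t.gene_id, np.zeros(T))
            per_gene[t.gene_id] += np.ma.filled(t.rpm, 0.0)
        return per_gene

    ref_genes = gene_matrix(ref)
    warp_paths = {}
    aligned_profiles: dict[str, dict[str, np.ndarray]] = {}
    for sp in spec.taxa[1:]:
        sp_genes = gene_matrix(sp)
        shared = sorted(set(ref_genes) & set(sp_genes))
        if len(shared) < 3:
            raise PipelineError("warp", f"fewer than 3 shared genes with {sp}")
        A = np.vstack([ref_genes[g] for g in shared])
        B = np.vstack([sp_genes[g] for g in shared])
        pa = preprocess([Profile(row) for row in A], upsample=config.upsample,
                        smooth_hr=config.smooth_pre)
        pb = preprocess([Profile(row) for row in B], upsample=config.upsample,
                        smooth_hr=config.smooth_pre)
        D = distance_matrix(np.vstack([p.values for p in pa]),
                            np.vstack([p.values for p in pb]))
        path = dtw_align(D, pa[0].hours, pb[0].hours, band_hr=config.band)
        warp_paths[sp] = path
        pio.write_warp_path(path, out / f"{ref}_vs_{sp}.warp.tsv")
        # transfer individual TSC profiles of syntenic promoters
        aligned_profiles[sp] = {}
        for g in shared:
            prof = preprocess([Profile(sp_genes[g])],
                              upsample=config.upsample,
                              smooth_hr=config.smooth_pre)[0]
            aligned_profiles[sp][g] = apply_warp(
                prof.values, path, smooth_hr=config.smooth_post)
    results["warp_paths"] = warp_paths

    # ---- classification --------------------------------------------------
    ref_profiles = {t.id: np.ma.filled(t.rpm, 0.0) for t in tsc_sets[ref]
                    if t.rpm is not None}
    classes = {tid: classify_hk_dev(v, min_max_rpm=config.min_max_rpm,
                                    hk_fold=config.hk_fold,
                                    dev_frac=config.dev_frac,
                                    window_hr=config.dev_window_hr)
               for tid, v in ref_profiles.items()}
    dev_ids = [tid for tid, c in classes.items() if c.label == "developmental"]
    labels = None
    if dev_ids:
        X = np.vstack([ref_profiles[tid] for tid in dev_ids])
        k = config.k
        if k > len(dev_ids):
            raise PipelineError(
                "classify", f"k={k} clusters requested but only "
                f"{len(dev_ids)} developmental profiles are available")
        labels = cluster_profiles(X, k=k, min_size=config.min_cluster,
                                  hours=np.arange(T) + 0.5)
        for tid, lab in zip(dev_ids, labels):
            classes[tid].cluster = int(lab) if lab >= 0 else None
    class_df = pd.DataFrame(
        [{"id": tid, "label": c.label,
          "cluster": c.cluster if c.cluster is not None else ""}
         for tid, c in classes.items()]).set_index("id")
    class_df.to_csv(out / "expression_classes.tsv", sep="\t")
    results["classes"] = classes

    # profile conservation across the clade (gene level, aligned grids)
    cons_rows = {}
    ref_pre = {g: preprocess([Profile(v)], upsample=config.upsample,
                             smooth_hr=config.smooth_pre)[0].values
               for g, v in ref_genes.items()}
    for g in ref_genes:
        stack = [ref_pre[g]]
        for sp in spec.taxa[1:]:
            if g in aligned_profiles[sp]:
                stack.append(aligned_profiles[sp][g])
        if len(stack) >= 2:
            cons_rows[g] = profile_conservation(np.vstack(stack))
    results["profile_conservation"] = cons_rows

    # entropy of reference profiles
    entropies = {}
    for tid, v in ref_profiles.items():
        if v.max() >= config.entropy_min_max_rpm and v.sum() > 0:
            entropies[tid] = shannon_entropy(v, min_max_rpm=config.entropy_min_max_rpm)
    results["entropy"] = entropies

    # ---- motifs ----------------------------------------------------------
    flank = config.motif_window // 2
    genome = clade.genomes[ref]["chr1"]
    windows = {}
    for t in tsc_sets[ref]:
        if t.main_tss is None:
            continue
        s, e = t.main_tss - flank, t.main_tss + flank + 1
        if s < 0 or e > len(genome):
            continue
        win = genome[s:e]
        if t.strand == "-":
            win = win.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        windows[t.id] = win
    pwms = core_promoter_pwms()
    scores, presence = scan_promoters(windows, pwms, pvalue=config.motif_pvalue)
    scores.to_csv(out / "motif_scores.tsv", sep="\t")
    results["motif_scores"] = scores
    results["motif_presence"] = presence

    # enrichment across expression clusters (clustered promoters only)
    clustered = [tid for tid in presence.index
                 if tid in classes and classes[tid].cluster is not None]
    if clustered and len({classes[t].cluster for t in clustered}) >= 2:
        groups = pd.Series({t: classes[t].cluster for t in clustered})
        enr = enrichment(presence.loc[clustered], groups)
        enr.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = enr

    # QDA phase prediction using timing-based phase labels per cluster
    phase_of = _phase_by_peak_time(classes, ref_profiles, T)
    labeled = [tid for tid in presence.index if phase_of.get(tid)]
    counts = pd.Series([phase_of[t] for t in labeled]).value_counts()
    if len(counts) == 3 and counts.min() >= scores.shape[1] + 2:
        qda = qda_phase_classifier(scores.loc[labeled],
                                   pd.Series({t: phase_of[t] for t in labeled}))
        results["qda"] = qda
        qda.confusion.to_csv(out / "qda_confusion.tsv", sep="\t")

    # ---- provenance ------------------------------------------------------
    provenance = {"config_hash": config.hash(), "seed": config.seed,
                  "python": sys.version.split()[0],
                  "stages": ["simulate", "call", "quantify", "assign",
                             "conserve", "matrix", "tree", "warp",
                             "classify", "entropy", "motifs"]}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    return results


def _phase_by_peak_time(classes: dict, profiles: dict, T: int,
                        boundaries: tuple = (7.0, 17.0)) -> dict:
    """Timing-based phase labels: peak hour before 7 h = Early, before 17 h
    = Intermediate, later = Late; housekeeping promoters are Early-phase
    (maternal/housekeeping class)."""
    hours = np.arange(T) + 0.5
    out = {}
    for tid, c in classes.items():
        if c.label == "unclassified":
            continue
        if c.label == "housekeeping":
            out[tid] = "Early"
            continue
        peak = hours[int(np.argmax(profiles[tid]))]
        if peak < boundaries[0]:
            out[tid] = "Early"
        elif peak < boundaries[1]:
            out[tid] = "Intermediate"
        else:
            out[tid] = "Late"
        classes[tid].phase = out[tid]
    return out
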