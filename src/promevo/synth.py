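"""Synthetic clade generator for end-to-end testing of the pipeline.

Emulates the study design the pipeline targets: a 5-species clade profiled
at 24 hourly time points of embryogenesis with 5'-end tag counts.  Promoters
sit at fixed loci of a shared ancestral coordinate frame; presence evolves
along a known tree by per-branch gain/loss events; temporal activity follows
Early / Intermediate / Late template families (maternal decay, mid-embryonic
peak, terminal rise) plus flat housekeeping profiles; species time axes are
distorted by piecewise-linear monotone warps; tags are Poisson-sampled and
spread around the main TSS by a discretized Gaussian; genomes carry
phase-dependent core-promoter motifs; alignment maps include assembly gaps,
alignment gaps and synteny breaks.

Everything is deterministic given the spec seed: per-species and per-stage
substreams are spawned from it.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from .motifs import CORE_MOTIF_CONSENSUS, IUPAC
from .tsc import TagTrack, Transcript, pool_tracks
from .xspecies import (STATUS_ALNGAP, STATUS_ASMGAP, STATUS_ORTH,
                       AlignmentMap, MapBlock)

__all__ = ["CladeSpec", "GroundTruth", "SimulatedClade", "simulate_clade",
           "simulate_replicates", "simulate_presence", "simulate_characters",
           "piecewise_linear_warp", "DEFAULT_TAXA", "DEFAULT_TREE"]

DEFAULT_TAXA = ("mel", "sim", "ere", "ana", "pse")
# rooted form of the drosophilid-like topology used for simulation;
# its unrooted version is what tree reconstruction should recover
DEFAULT_TREE = ((("mel", "sim"), "ere"), ("ana", "pse"))

PHASES = ("Early", "Intermediate", "Late")

# characteristic positions of core motifs relative to the main TSS
MOTIF_OFFSETS = {
    "TATA": -30, "INR": -2, "DPE": 27, "MTE": 20, "DRE": -55,
    "Ohler1": -45, "Ohler5": -70, "Ohler6": -60, "Ohler7": -40, "TCT": -2,
}

# phase-dependent motif embedding probabilities; housekeeping promoters use
# the Early model (maternal/housekeeping promoters share the DRE/Ohler class)
DEFAULT_MOTIF_MODEL = {
    "Early": {"DRE": 0.6, "Ohler1": 0.5, "Ohler6": 0.4, "Ohler7": 0.35},
    "Intermediate": {"INR": 0.7, "DPE": 0.5, "MTE": 0.4},
    "Late": {"TATA": 0.7, "INR": 0.4},
}

DEFAULT_INDEL_MODEL = {
    "assembly_gap": 0.02,   # per locus, per species: ~100 bp of missing assembly
    "alignment_gap": 0.05,  # per locus: an unalignable stretch
    "synteny_break": 0.02,  # per locus: downstream flank maps elsewhere
}


def _tree_leaves(node) -> tuple:
    if isinstance(node, str):
        return (node,)
    out = ()
    for child in node:
        out += _tree_leaves(child)
    return out


def _tree_branches(node, out=None) -> list:
    """All (parent_node, child_node) edges of the rooted simulation tree."""
    if out is None:
        out = []
    if isinstance(node, str):
        return out
    for child in node:
        out.append((node, child))
        _tree_branches(child, out)
    return out


def _branch_key(child) -> tuple:
    """Stable identifier of a branch: the sorted leaf set below it."""
    return tuple(sorted(_tree_leaves(child)))


@dataclass
class CladeSpec:
    """Full parameterization of a synthetic clade.

    Defaults mirror the study design: 5 taxa on the known drosophilid-like
    topology, 24 hourly time points (point k sampled at hour k + 0.5), and
    narrow promoters (sigma = 10 bp of initiation scatter).  ``depth`` is the
    expected total tag count per library; the desk-scale default keeps a
    full clade simulation fast while giving several hundred tags per
    promoter over a time course.  ``gain``/``loss`` are per-branch event
    probabilities (scalars apply to every branch; dicts are keyed by the
    sorted leaf tuple below the branch).
    """

    taxa: tuple = DEFAULT_TAXA
    tree: tuple = DEFAULT_TREE
    n_tscs: int = 300
    time_points: int = 24
    depth: float = 5e4
    gain: float | dict = 0.03
    loss: float | dict = 0.08
    warp_params: dict = field(default_factory=dict)  # species -> knot list
    motif_model: dict = field(default_factory=lambda: DEFAULT_MOTIF_MODEL)
    indel_model: dict = field(default_factory=lambda: dict(DEFAULT_INDEL_MODEL))
    sigma_tss: float = 10.0
    overdispersion: float = 0.0  # Gamma-Poisson mixing; 0 = pure Poisson
    hk_frac: float = 0.1
    phase_probs: tuple = (0.25, 0.55, 0.20)  # Early / Intermediate / Late
    genic_frac: float = 0.7
    minus_strand_frac: float = 0.3
    spacing: int = 1000
    motif_turnover: float = 0.05
    root_absent_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        leaves = tuple(sorted(_tree_leaves(self.tree)))
        if leaves != tuple(sorted(self.taxa)):
            raise ValueError("tree leaf set does not match taxa")
        if not _is_binary(self.tree):
            raise ValueError("simulation tree must be binary")
        for p in self._branch_probs("gain").values():
            if not 0 <= p <= 1:
                raise ValueError("gain probabilities must lie in [0, 1]")
        for p in self._branch_probs("loss").values():
            if not 0 <= p <= 1:
                raise ValueError("loss probabilities must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        T = self.time_points
        for sp, knots in self.warp_params.items():
            hrs = [k[0] for k in knots]
            refs = [k[1] for k in knots]
            if sorted(hrs) != hrs or sorted(refs) != refs or \
                    len(set(hrs)) != len(hrs) or len(set(refs)) != len(refs):
                raise ValueError(f"warp for {sp} must be strictly increasing")
            if min(hrs) < 0 or max(hrs) > T:
                raise ValueError(f"warp knots for {sp} must lie in [0, {T}]")

    def _branch_probs(self, kind: str) -> dict:
        val = getattr(self, kind)
        branches = [_branch_key(c) for _, c in _tree_branches(self.tree)]
        if isinstance(val, dict):
            return {b: float(val.get(b, 0.0)) for b in branches}
        return {b: float(val) for b in branches}

    @property
    def hours(self) -> np.ndarray:
        return np.arange(self.time_points) + 0.5

    def locus_tss(self, i: int) -> int:
        return self.spacing // 2 + i * self.spacing

    @property
    def genome_length(self) -> int:
        return self.n_tscs * self.spacing


def _is_binary(node) -> bool:
    if isinstance(node, str):
        return True
    return len(node) == 2 and all(_is_binary(c) for c in node)


def piecewise_linear_warp(knots: list[tuple[float, float]]):
    """Monotone piecewise-linear map from species time to reference time.

    ``knots`` are (species_hour, reference_hour) pairs, strictly increasing
    in both coordinates; evaluation interpolates linearly and extrapolates
    with the boundary slopes clipped to the knot range.
    """
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)

    def warp(t):
        return np.interp(t, xs, ys)

    warp.knots = list(knots)
    return warp


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    presence: np.ndarray          # (n_taxa, n_tscs) 0/1
    alignable: np.ndarray         # (n_taxa, n_tscs) bool: syntenic to reference
    taxa: list
    tree: tuple
    phases: list                  # per TSC: 'HK' or a phase name
    classes: list                 # per TSC: 'housekeeping' | 'developmental'
    main_tss: np.ndarray          # shared locus TSS coordinate per TSC
    strands: list
    warps: dict                   # species -> warp function (knots attached)
    intensities: dict             # species -> (n_tscs, T) expected tag counts
    profiles: np.ndarray          # (n_tscs, T) reference-time template values
    gene_ids: list                # per TSC: gene id or None (orphan)
    n_events: np.ndarray          # gain+loss events simulated per TSC

    def intervals(self, species_idx: int, halfwidth: int = 100) -> list:
        """True promoter intervals for one species (present TSCs only)."""
        out = []
        for i in np.flatnonzero(self.presence[species_idx]):
            tss = int(self.main_tss[i])
            out.append((i, tss - halfwidth, tss + halfwidth + 1, self.strands[i]))
        return out


@dataclass
class SimulatedClade:
    spec: CladeSpec
    tracks: dict      # species -> time point -> strand -> TagTrack
    pooled: dict      # species -> strand -> TagTrack
    genomes: dict     # species -> {contig: sequence}
    maps: dict        # non-reference species -> AlignmentMap (reference frame)
    transcripts: list # annotated transcripts on the reference layout
    truth: GroundTruth

    @property
    def ref_species(self) -> str:
        return self.spec.taxa[0]


# ---------------------------------------------------------------------------
# evolution of presence/absence


def simulate_presence(spec: CladeSpec, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Evolve per-TSC presence along the tree.

    Returns ``(presence, n_events)``: presence is (n_taxa, n_tscs) in the
    order of ``spec.taxa``; n_events counts simulated flips per character.
    """
    n = spec.n_tscs
    gain = spec._branch_probs("gain")
    loss = spec._branch_probs("loss")
    root = (rng.random(n) >= spec.root_absent_frac).astype(np.int8)
    states = {id(spec.tree): root}
    events = np.zeros(n, dtype=int)
    leaf_states: dict[str, np.ndarray] = {}

    def descend(node, parent_state):
        for child in (node if not isinstance(node, str) else ()):
            key = _branch_key(child)
            u = rng.random(n)
            child_state = np.where(
                parent_state == 1,
                (u >= loss[key]).astype(np.int8),
                (u < gain[key]).astype(np.int8))
            events[child_state != parent_state] += 1
            if isinstance(child, str):
                leaf_states[child] = child_state
            else:
                descend(child, child_state)

    descend(spec.tree, root)
    presence = np.vstack([leaf_states[t] for t in spec.taxa])
    return presence, events


def simulate_characters(tree: tuple, taxa: tuple, n_chars: int,
                        rng: np.random.Generator,
                        informative_only: bool = True) -> np.ndarray:
    """Characters with exactly one event each, for clean tree recovery.

    Each character picks one branch uniformly and flips the subtree below
    it relative to a present root.  With ``informative_only`` the branch is
    drawn from internal branches only, so every character is parsimony-
    informative on the generating topology.
    """
    branches = [_branch_key(c) for _, c in _tree_branches(tree)]
    if informative_only:
        branches = [b for b in branches
                    if 2 <= len(b) <= len(taxa) - 2]
    states = np.ones((len(taxa), n_chars), dtype=np.int8)
    idx = {t: i for i, t in enumerate(taxa)}
    choice = rng.integers(0, len(branches), n_chars)
    for j in range(n_chars):
        for t in branches[choice[j]]:
            states[idx[t], j] = 0
    return states


# ---------------------------------------------------------------------------
# temporal profiles


def _sample_profiles(spec: CladeSpec, rng: np.random.Generator):
    """Phase labels and reference-time intensity templates per TSC."""
    n, T = spec.n_tscs, spec.time_points
    t = spec.hours
    labels = []
    profiles = np.empty((n, T))
    for i in range(n):
        if rng.random() < spec.hk_frac:
            labels.append("HK")
            profiles[i] = 1.0 + 0.05 * rng.standard_normal(T).clip(-2, 2)
            continue
        phase = PHASES[rng.choice(3, p=np.asarray(spec.phase_probs)
                                  / np.sum(spec.phase_probs))]
        labels.append(phase)
        if phase == "Early":          # maternal decay
            tau = rng.uniform(2.0, 5.0)
            profiles[i] = np.exp(-t / tau)
        elif phase == "Intermediate": # mid-embryogenesis peak
            mu = rng.uniform(8.0, 16.0)
            sd = rng.uniform(1.5, 3.0)
            profiles[i] = np.exp(-0.5 * ((t - mu) / sd) ** 2)
        else:                         # terminal rise
            mu = rng.uniform(18.0, 22.0)
            profiles[i] = 1.0 / (1.0 + np.exp(-(t - mu) / 1.0))
        profiles[i] = np.maximum(profiles[i], 1e-4)
    return labels, profiles


def _profile_at(profiles_fn_t: np.ndarray, spec: CladeSpec, warped_hours):
    """Evaluate the hourly template at arbitrary (warped) hours."""
    return np.stack([np.interp(warped_hours, spec.hours, row)
                     for row in profiles_fn_t])


# ---------------------------------------------------------------------------
# tag sampling


def _place_tags(spec: CladeSpec, rng: np.random.Generator,
                tss: np.ndarray, strands: np.ndarray,
                counts: np.ndarray, species: str, contig: str,
                time_point: int | None) -> dict[str, TagTrack]:
    """Scatter per-TSC tag counts into per-base stranded tracks."""
    cap = int(min(80, spec.spacing // 2 - 10))  # keep mass within ~<=200 bp
    tracks = {}
    total_all = int(counts.sum())
    centers = np.repeat(tss, counts)
    strand_rep = np.repeat(strands, counts)
    offsets = np.rint(rng.normal(0.0, spec.sigma_tss, total_all)).astype(np.int64)
    offsets = np.clip(offsets, -cap, cap)
    pos = centers + offsets
    lib = total_all
    for s in ("+", "-"):
        sel = strand_rep == s
        upos, uval = np.unique(pos[sel], return_counts=True)
        tracks[s] = TagTrack(species, contig, s, (upos, uval),
                             library_size=lib, time_point=time_point)
    return tracks


def _poisson(rng: np.random.Generator, lam: np.ndarray,
             overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        # Gamma-Poisson: variance = mean * (1 + overdispersion * mean)
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, 1.0, size=lam.shape) * overdispersion * lam
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# genomes, motifs, alignment maps


_COMP = str.maketrans("ACGT", "TGCA")


def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in consensus)


def _make_genome(spec: CladeSpec, rng: np.random.Generator,
                 present: np.ndarray, strands: np.ndarray,
                 tss: np.ndarray, embeddings: list[dict[str, str]]) -> str:
    seq = rng.choice(list("ACGT"), size=spec.genome_length)
    for i in np.flatnonzero(present):
        for motif, realization in embeddings[i].items():
            off = MOTIF_OFFSETS[motif]
            if strands[i] == "+":
                start = tss[i] + off
                word = realization
            else:
                word = realization.translate(_COMP)[::-1]
                start = tss[i] - off - len(word) + 1
            if 0 <= start and start + len(word) <= seq.size:
                seq[start:start + len(word)] = list(word)
    return "".join(seq)


def _make_map(spec: CladeSpec, rng: np.random.Generator, ref: str,
              target: str) -> tuple[AlignmentMap, np.ndarray]:
    """Identity-frame map from reference to target with simulated lesions.

    Returns the map plus a per-TSC boolean 'designed alignable' vector
    (False where a synteny break was injected at the locus).
    """
    L = spec.genome_length
    status = np.zeros(L, dtype=np.uint8)  # all orthologous
    break_contig = np.zeros(L, dtype=bool)
    rates = spec.indel_model
    alignable = np.ones(spec.n_tscs, dtype=bool)
    for i in range(spec.n_tscs):
        lo = i * spec.spacing
        tss = spec.locus_tss(i)
        # gap lesions are placed clear of the 800 bp window endpoints so the
        # designed-alignable flag stays the truth of the syntenic filter
        if rng.random() < rates.get("assembly_gap", 0.0):
            s = rng.integers(lo + 150, lo + 700)
            status[s:s + 100] = STATUS_ASMGAP
        if rng.random() < rates.get("alignment_gap", 0.0):
            s = rng.integers(lo + 150, lo + 700)
            status[s:s + 100] = STATUS_ALNGAP
        if rng.random() < rates.get("synteny_break", 0.0):
            # downstream flank maps to another contig: the 800 bp synteny
            # window around the TSS straddles the break and must fail
            break_contig[tss:min(tss + 500, L)] = True
            alignable[i] = False
    blocks: list[MapBlock] = []
    # cut [0, L) into runs homogeneous in (status class, break flag)
    run_id = status.astype(np.int64) * 2 + break_contig
    change = np.flatnonzero(np.diff(run_id)) + 1
    bounds = np.concatenate(([0], change, [L]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        st = int(status[s])
        onbreak = bool(break_contig[s])
        contig = "chrU" if onbreak else "chr1"
        if st == STATUS_ORTH:
            blocks.append(MapBlock("chr1", int(s), int(e), contig, int(s),
                                   int(e), "+", np.zeros(e - s, np.uint8)))
        else:
            blocks.append(MapBlock("chr1", int(s), int(e), contig, int(s),
                                   int(s), "+",
                                   np.full(e - s, st, np.uint8)))
    return AlignmentMap(ref, target, blocks), alignable


# ---------------------------------------------------------------------------
# top-level simulation


def _default_warps(spec: CladeSpec, rng: np.random.Generator) -> dict:
    """Per-species monotone time maps; the reference gets the identity."""
    T = spec.time_points
    warps = {}
    for k, sp in enumerate(spec.taxa):
        if sp in spec.warp_params:
            warps[sp] = piecewise_linear_warp(spec.warp_params[sp])
        elif k == 0:
            warps[sp] = piecewise_linear_warp([(0.0, 0.0), (float(T), float(T))])
        else:
            d1, d2 = rng.uniform(-2.0, 2.0, 2)
            knots = [(0.0, 0.0), (T / 3, np.clip(T / 3 + d1, 0.5, T - 0.5)),
                     (2 * T / 3, np.clip(2 * T / 3 + d2, 1.0, T - 0.25)),
                     (float(T), float(T))]
            xs = [k[1] for k in knots]
            if sorted(xs) != xs or len(set(xs)) != len(xs):  # keep monotone
                knots = [(0.0, 0.0), (float(T), float(T))]
            warps[sp] = piecewise_linear_warp(knots)
    return warps


def simulate_clade(spec: CladeSpec) -> SimulatedClade:
    """Generate a fully specified synthetic clade.

    Deterministic given ``spec.seed``; per-species substreams are spawned
    from the master seed so adding analyses never perturbs earlier draws.
    """
    master = np.random.SeedSequence(spec.seed)
    (s_layout, s_presence, s_profiles, s_warps, s_genomes, s_maps,
     s_tags) = master.spawn(7)
    rng_layout = np.random.default_rng(s_layout)
    n, T = spec.n_tscs, spec.time_points

    # layout: fixed loci shared across the clade
    tss = np.array([spec.locus_tss(i) for i in range(n)])
    strands = np.where(rng_layout.random(n) < spec.minus_strand_frac, "-", "+")
    genic = rng_layout.random(n) < spec.genic_frac
    gene_ids = [f"g{i:05d}" if genic[i] else None for i in range(n)]

    presence, n_events = simulate_presence(
        spec, np.random.default_rng(s_presence))
    rng_prof = np.random.default_rng(s_profiles)
    phase_labels, profiles = _sample_profiles(spec, rng_prof)
    classes = ["housekeeping" if p == "HK" else "developmental"
               for p in phase_labels]
    weights = rng_prof.lognormal(mean=0.0, sigma=1.0, size=n)

    warps = _default_warps(spec, np.random.default_rng(s_warps))

    # motif embeddings decided once at the root, inherited by all species
    rng_gen = np.random.default_rng(s_genomes)
    embeddings: list[dict[str, str]] = []
    for i in range(n):
        model = spec.motif_model.get(
            "Early" if phase_labels[i] == "HK" else phase_labels[i], {})
        emb = {m: _realize_iupac(CORE_MOTIF_CONSENSUS[m], rng_gen)
               for m, p in model.items() if rng_gen.random() < p}
        embeddings.append(emb)

    tracks: dict = {}
    pooled: dict = {}
    genomes: dict = {}
    maps: dict = {}
    intensities: dict = {}
    alignable = np.ones((len(spec.taxa), n), dtype=bool)
    rng_maps = np.random.default_rng(s_maps)
    tag_seeds = s_tags.spawn(len(spec.taxa))

    for k, sp in enumerate(spec.taxa):
        rng_sp = np.random.default_rng(tag_seeds[k])
        warped = warps[sp](spec.hours)
        prof_sp = _profile_at(profiles, spec, warped)
        # normalize over the species' own present promoters so every
        # library's expected total is the configured depth
        weighted = weights[:, None] * prof_sp * presence[k][:, None]
        norm = weighted.sum(axis=0).mean()
        lam = spec.depth * weighted / norm
        intensities[sp] = lam
        tracks[sp] = {}
        for t in range(T):
            counts = _poisson(rng_sp, lam[:, t], spec.overdispersion)
            tracks[sp][t] = _place_tags(spec, rng_sp, tss, strands, counts,
                                        sp, "chr1", t)
        pooled[sp] = {s: pool_tracks([tracks[sp][t][s] for t in range(T)])
                      for s in ("+", "-")}
        # per-species motif turnover: lost/absent promoters keep background
        emb_sp = []
        for i in range(n):
            if presence[k][i] == 0:
                emb_sp.append({})
                continue
            emb_sp.append({m: r for m, r in embeddings[i].items()
                           if rng_gen.random() >= spec.motif_turnover})
        genomes[sp] = {"chr1": _make_genome(spec,
                                            np.random.default_rng(
                                                s_genomes.spawn(1)[0]),
                                            np.ones(n, bool), strands, tss,
                                            emb_sp)}
        if k > 0:
            maps[sp], align_sp = _make_map(spec, rng_maps, spec.taxa[0], sp)
            alignable[k] = align_sp

    transcripts = [
        Transcript(gene_ids[i], f"{gene_ids[i]}.t1", "chr1", strands[i],
                   int(tss[i]))
        for i in range(n) if gene_ids[i] is not None
    ]

    truth = GroundTruth(presence=presence, alignable=alignable,
                        taxa=list(spec.taxa), tree=spec.tree,
                        phases=phase_labels, classes=classes,
                        main_tss=tss, strands=list(strands),
                        warps=warps, intensities=intensities,
                        profiles=profiles, gene_ids=gene_ids,
                        n_events=n_events)
    return SimulatedClade(spec=spec, tracks=tracks, pooled=pooled,
                          genomes=genomes, maps=maps,
                          transcripts=transcripts, truth=truth)


def simulate_replicates(intensities: np.ndarray, seed: int = 0,
                        spec: CladeSpec | None = None,
                        species: str = "mel"):
    """Two independent Poisson replicates of the same promoter intensities.

    ``intensities`` is (n_tscs, T) of expected tag counts.  Returns
    ``(tracks_a, tracks_b, counts_a, counts_b)`` where the track dicts map
    time point -> strand -> TagTrack on the standard synthetic layout (all
    promoters on the '+' strand unless a spec provides one) and the count
    arrays hold the sampled per-TSC per-time-point tags.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    if np.any(intensities < 0):
        raise ValueError("intensities must be nonnegative")
    n, T = intensities.shape
    if spec is None:
        spec = CladeSpec(n_tscs=n, time_points=T, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tss = np.array([spec.locus_tss(i) for i in range(n)])
    strands = np.full(n, "+")
    out_tracks = []
    out_counts = []
    for _rep in range(2):
        counts = rng.poisson(intensities)
        rep_tracks = {}
        for t in range(T):
            rep_tracks[t] = _place_tags(spec, rng, tss, strands,
                                        counts[:, t], species, "chr1", t)
        out_tracks.append(rep_tracks)
        out_counts.append(counts)
    return out_tracks[0], out_tracks[1], out_counts[0], out_counts[1]
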