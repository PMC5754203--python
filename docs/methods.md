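# Methods

This note documents the models, parameter choices and numerical decisions
behind `promevo`, and what the synthetic-data tests do and do not
demonstrate about real data.

## TSC calling

Promoters in 5'-tag data appear as narrow clusters of initiation positions.
The caller operates on the time-pooled track per strand: positions with at
least `min_pos_count` (default 2) tags anchor clusters; anchor runs
separated by at most `max_gap` (50 bp) intervening bases merge; the cluster
interval spans first to last anchor and is kept when the tags inside it
(including sub-threshold positions) reach `min_total` (15). The published
assay's own peak caller is described only in prior work, so these defaults
are package choices: a 2-tag anchor suppresses singleton noise, 50 bp
matches the scale of multi-position initiation, and 15 total tags aligns
the calling floor with the conservation-eligibility filter so that every
called TSC is also testable across species. All three are configurable.
Calling is idempotent, commutes with coordinate translation, and strands
never merge (no bidirectional-promoter joining).

The main TSS is the most heavily used base; ties break to the 5'-most
position on the TSC's strand, which makes downstream motif windows
deterministic. Per-time-point quantification records counts and RPM
(counts / library size × 10⁶); missing libraries are carried as masked
values, never zeros, and are only interpolated transiently inside warp
preprocessing.

Gene assignment follows the transcript-5'-end rule: a transcript matches a
TSC when its annotated 5' end lies within `tss_match` (150 bp) of the TSC
interval on the same strand; nearest end wins, exact ties break
lexicographically on gene id (logged). Everything else is an orphan —
the candidate noncoding class.

## Cross-species projection and conservation

The multi-genome alignment is abstracted to pairwise maps from one
reference frame to each target. Each map block carries a per-reference-base
status — orthologous, alignment gap, or assembly gap — because the
syntenic filter needs to distinguish "the target genome has no sequence
here" (assembly gap) from "the sequences do not align" (alignment gap);
chain formats cannot express this, hence the run-length-encoded TSV
dialect. Within a block the k-th orthologous base maps to the k-th target
base, reversed on '-' blocks, so projection and its inverse are exact on
orthologous bases.

The syntenic filter takes an 800 bp window centered on the TSC midpoint and
requires (i) both window endpoints in blocks of the same target contig and
strand, (ii) ≥ 50% of window bases aligned, (iii) ≥ 25% orthologous. We
count unaligned (outside-block) bases as not aligned for criterion (ii):
in a genuine multiple alignment every base is present and "not aligned"
means assembly gap, but with pairwise maps an uncovered base carries the
same meaning, so the substantive rule — half the window must have target
sequence — is preserved. All boundaries are inclusive.

The conservation caller compares raw tag counts by default (a
depth-normalization flag exists but is off, following the source analysis
literally; synthetic libraries share a common depth, so the choice is
inert there): with ≥ 100 reference tags, absent iff the target signal is
at least 100-fold lower (boundary inclusive); with 15–99 reference tags,
absent iff the target shows zero tags over the whole time course.
Promoters under 15 tags are excluded upstream and the caller refuses them.
Monotonicity (more target signal can never flip present → absent) is a
tested invariant. Subclade summaries report both conventions — conserved
fraction of all eligible TSCs, and of syntenically alignable ones — since
the two bracket the truth.

The non-redundant cross-species peak set projects every species' TSCs into
the reference frame and merges same-strand groups overlapping by ≥ 1 bp
into one character; a taxon scores 1 if it contributed a TSC, '?' if the
region is not alignable to it, else 0. Target TSCs that cannot reach the
reference frame become own characters with '?' elsewhere (honest missing
data; such singletons are parsimony-uninformative either way).

Sequence-conservation summaries consume score tracks as inputs:
metaprofiles are per-position medians with a bootstrap SE envelope;
selection fractions count bases with phyloP > 0.1 (purifying) or < −0.1
(faster than neutral); profile-vs-sequence conservation correlations are
computed on unbinned per-TSC values, with quantile binning used for
display only. Subregion bands relative to the main TSS default to
Upstream −300..−50 (the documented extent), TATA −40..−20, Inr −10..+10,
DPE +20..+40, Downstream +50..+150; only the upstream band has a quoted
extent, the rest bracket the canonical motif positions and are
configurable.

## Parsimony phylogeny

Presence/absence characters are scored by Fitch counting, vectorized
across characters with state bitmasks; '?' enters as the full state set,
which for unordered binary characters yields the minimum over assignments.
For two-state unordered characters Wagner and Fitch parsimony coincide, so
a single implementation covers the mixed-method workflow of the original
analysis. Up to 9 taxa, all (2n−5)!! unrooted topologies are enumerated
(15 for the 5-taxon design) and scored; ties are returned in canonical
newick order. Beyond 9 taxa the search refuses and points to dedicated
software — heuristic search is out of scope. Correctness is pinned by an
exhaustive internal-state-assignment oracle in the tests.

## Time-series registration

Registration assumes the two species run the same developmental program at
smoothly varying relative pace, so a monotone time map aligns them.
Gene-level profiles (summed TSC RPM per gene) are z-scored, linearly
upsampled 5-fold ((T−1)·5 + 1 grid points; 116 for T = 24) and smoothed
with a centered 2 hr moving average that shrinks at the edges. The
distance between reference time i and target time j is 1 − Pearson r of
the cross-gene expression vectors; zero-variance time points get maximal
distance 2 (logged). Global DTW with steps {(1,0),(0,1),(1,1)} under a
Sakoe–Chiba band of 3 hr finds the optimal path; ties prefer the diagonal,
making the path deterministic. The band is interpreted as a hard path
constraint — the original tooling's "3 hr window" is not further
documented, and a band constraint matches its stated inputs and outputs.
The recovered path then transfers individual promoter profiles: each
reference grid point averages its matched target values, followed by 1 hr
smoothing. Self-alignment returns the identity path and warping preserves
peak order; on noiseless inputs, aligning a synthetically warped series
back restores r ≥ 0.95 against the original.

## Expression classes and statistics

A promoter whose profile maximum falls under `min_max_rpm` (10 RPM) is
unclassified — below that, replicate reproducibility is too weak to trust
the shape. Housekeeping: max/min < 5 over unmasked points (a zero minimum
means unbounded fold change, hence never housekeeping). Developmental: the
best window of 8 consecutive hourly points holds ≥ 60% of the profile sum.
A profile can satisfy both (low fold change concentrated in 8 hr);
housekeeping takes precedence, keeping the classes disjoint — the source
presents them as disjoint without stating an order, and the HK criterion
is the stricter statement about overall variation. Profiles meeting
neither stay unclassified.

Developmental profiles cluster hierarchically on 1 − r distance with
complete linkage (scipy), cut into k = 12 groups; groups under
`min_cluster` (200 at study scale; scaled down in desk-size demos) are
dropped and survivors renumber by mean peak time. Profile conservation
across a clade is the mean pairwise Pearson R² — taken literally, so an
exactly anti-correlated pair scores as conserved; a signed-r² option
(sign(r)·r²) exists but is off, since the literal definition is the
documented one. Divergence is 1 minus conservation. Shannon entropy of the
normalized profile (0·log 0 = 0) measures stage-specificity in bits,
0 to log₂ T; it applies above a 2 RPM maximum. Replicate concordance is
the squared Pearson correlation of paired per-time-point values within
max-RPM strata (10 and 25 RPM by default).

## Motif analysis

PWMs carry probabilities with pseudocount normalization, a background
distribution and a strand policy. Core promoter elements are
TSS-orientation-specific, so they scan sense-only; TFBS matrices scan both
strands. Scores are summed log₂ odds; non-ACGT bases contribute 0.
Presence thresholds derive from p-values under the i.i.d. background null:
the exact score distribution is built by dynamic programming on an integer
grid (1/1000 bit; discretization error ≤ L/2000 bits), and the threshold
is the smallest *achievable* score whose tail probability is ≤ p — the
convention standard scanners use, and the one an exhaustive 4^L word
enumeration reproduces (a tested oracle for L ≤ 8). The default core-motif
presence p-value is 10⁻³ (the original cutoff is unpublished); the TFBS
search cutoff of 2×10⁻⁴ is kept as a config constant.

The bundled PWM set encodes compact degenerate consensus strings for TATA
(STATAAA), Initiator (TCAGTY), DPE (KCGGTTSK), MTE, DRE (TATCGATA),
Ohler-1/5/6/7 and TCT; the TATA/Inr/DPE strings are the canonical
published consensi, the others are short approximations suitable for
scanning and exact-null computation. JASPAR and MEME files can be
substituted, and a trivial IUPAC string matcher covers
consensus-string-only analyses.

Enrichment builds a 2×2 presence table per (motif, group), chi-square
without continuity correction, Fisher's exact test when an expected cell
drops below 5 (flagged), Benjamini–Hochberg across all tests. Two ratios
are reported: frequency in group over frequency in the other groups (the
displayed enrichment) and over the pooled frequency — only the latter has
the exact property that group-size-weighted ratios average to 1, so both
are kept. Co-occurrence grouping uses 1 − phi distance (phi = Pearson r of
the indicator vectors) with complete linkage; constant motifs are excluded.

Phase prediction uses Gaussian QDA with per-class covariance and a ridge
term λ = 10⁻³·trace/d on the diagonal for stability, on features
log(score − global_min + 1) (log-odds can be negative). Evaluation is
leave-one-out CV with per-true-class chi-square tests against uniform
chance, FDR-corrected. Phase labels come from grouping expression clusters
by peak timing (Early < 7 h, Intermediate < 17 h, Late otherwise;
housekeeping promoters join the Early/maternal class) — the synthetic
fallback for the enrichment-matrix-based grouping a full-size study would
use. The implementation agrees with scikit-learn's QDA on well-conditioned
data (tested); it exists separately because the ridge parameterization
differs.

Motif functional conservation compares presence in reference windows with
presence in orthologous target windows (obtained by projecting the main
TSS and extracting 301 bp). The baseline repeats the statistic with
column-shuffled PWMs; since the background null is i.i.d., a position
permutation leaves the null score distribution — hence the threshold —
unchanged, so shuffled motifs are scanned at the same cutoff.

## The synthetic clade generator

The generator defines the study conditions for all tests: 5 taxa on the
known drosophilid-like topology, 24 hourly time points (point k at hour
k + 0.5), promoters at fixed loci (1 kb spacing) of a shared ancestral
coordinate frame. Presence evolves root-to-tip with per-branch loss
(default 0.08) and gain (0.03) probabilities — rates chosen so that a
desk-scale clade shows the qualitative pattern of the real data:
conservation declining from ~90% for the closest pair to ~60% clade-wide,
between the two reporting conventions. Expression weights are lognormal
(σ = 1); temporal templates are three phase families — Early maternal
decay (exponential, τ ∈ [2, 5] h), Intermediate mid-embryonic peak
(Gaussian, center ∈ [8, 16] h), Late terminal rise (logistic, center ∈
[18, 22] h) — plus flat housekeeping profiles (10% of promoters; phase
mix 25/55/20). Species time axes are distorted by piecewise-linear
monotone warps with ≤ 3 interior knots and fixed endpoints, offsets up to
a few hours — the simplest family the DTW stage should recover. Tags are
Poisson-sampled per time point (a Gamma–Poisson overdispersion knob
exists, default off, since the assay's noise model is not published) and
scattered around the main TSS by a discretized Gaussian (σ = 10 bp,
truncated at ±80 bp so clusters stay within 200 bp). Per-species expected
library totals equal the configured depth (default 5×10⁴ per library at
desk scale), normalized over each species' present promoters.

Genomes are i.i.d. random sequence with phase-dependent core motifs
embedded at characteristic offsets (e.g. TATA at −30, DPE at +27),
decided once ancestrally and inherited with a small per-species turnover
(5%), so conserved promoters share motif content far above a shuffled
baseline. Alignment maps are identity maps with injected lesions: ~100 bp
assembly-gap and alignment-gap stretches (placed clear of the syntenic
window endpoints so the designed alignable flag is exact) and synteny
breaks that reroute a promoter's downstream flank to another contig,
guaranteeing a filter failure at that locus.

What the generator does not emulate: realistic genome composition beyond
the embedded motifs, sequencing error, mappability structure, replicate
batch effects, overdispersion (off by default), or correlated evolution
between neighboring promoters. Tests passing on this generator show the
pipeline's logic and numerics are correct under the stated model — not
that the biological thresholds are optimal for any particular real
dataset.

Determinism: one master seed; per-stage and per-species substreams are
spawned via `SeedSequence` so adding an analysis never perturbs earlier
draws; identical seeds reproduce byte-identical artifacts.

## Numerical and degenerate-input choices

- Zero-variance profiles z-score to zeros (logged) and take maximal
  Pearson distance where a correlation is required.
- Masked time points are linearly interpolated only inside warp
  preprocessing and re-masked afterwards.
- DTW ties prefer the diagonal step; enrichment ratio ∞ (motif absent
  outside the group) is reported as ∞ unless a cap is requested.
- Chi-square tests use no continuity correction; expected-count < 5
  tables fall back to Fisher's exact test, flagged per row.
- The permutation calibration of enrichment p-values is judged against a
  binomial confidence band around the nominal 5%, since the empirical
  false-positive rate of a calibrated test fluctuates around — and for
  discrete tables sits slightly below — its nominal level.
- All coordinates are 0-based half-open internally; BED output is
  compatible by construction.

## Desk-scale problem sizes

The package's own test and acceptance runs use: 10,000 promoters for the
replicate false-positive rate, 50 clades × ~210 informative characters for
tree recovery, 20 species pairs at 10⁷ tags/library for warp recovery
(120 genes per pair), 100 random instances per brute-force oracle, and
full-pipeline runs at 150–300 promoters. These sizes were chosen as the
smallest that leave comfortable statistical margins for each check.

## Known limitations

- The exhaustive tree search is exact but limited to 9 taxa.
- Only pairwise (reference-anchored) alignment maps are supported; a true
  multiple alignment would allow target-target comparisons without
  composing inverses.
- The QDA phase labels in the pipeline come from the timing-based
  fallback, not from enrichment-matrix clustering, which needs study-scale
  cluster counts.
- `harmonize_pair` rescues promoters one direction at a time; run it both
  ways for a symmetric harmonization.
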