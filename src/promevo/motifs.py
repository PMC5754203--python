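"""Core promoter motif and TFBS analysis.

Position weight matrices are scanned over 301 bp windows centered on each
promoter's main TSS.  Presence thresholds come either directly as log-odds
scores or from a p-value under the i.i.d.-background null (exact score
distribution by dynamic programming).  Downstream statistics: per-cluster
enrichments with FDR-corrected chi-square tests, motif co-occurrence
grouping, phase prediction by quadratic discriminant analysis with
leave-one-out cross-validation, and cross-species motif functional
conservation against a shuffled-matrix baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["PWM", "MotifHit", "core_promoter_pwms", "score_threshold",
           "pwm_scan", "scan_promoters", "enrichment",
           "cooccurrence_clusters", "qda_phase_classifier", "GaussianQDA",
           "motif_functional_conservation", "iupac_find"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position probability matrix with background and scan policy.

    ``probs`` is (L, 4) over A, C, G, T; rows sum to 1 after pseudocount
    normalization.  Core promoter motifs are orientation-specific relative
    to the TSS and scanned sense-only by default; TFBS matrices should use
    ``strand_policy='both'``.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = None
    pseudocount: float = 0.0
    strand_policy: str = "sense_only"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount:
            self.probs = self.probs + self.pseudocount
        self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)
        if self.strand_policy not in ("sense_only", "both"):
            raise ValueError("strand_policy must be 'sense_only' or 'both'")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2 odds; the 5th column (non-ACGT) scores 0."""
        lo = np.log2(self.probs / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.id + "_rc", self.probs[::-1, ::-1],
                   background=self.background[::-1],
                   strand_policy=self.strand_policy)

    def shuffled(self, rng: np.random.Generator) -> "PWM":
        """Column-shuffled control: positions permuted, multiset preserved."""
        perm = rng.permutation(len(self))
        if len(self) > 1:
            while np.array_equal(perm, np.arange(len(self))):
                perm = rng.permutation(len(self))
        return PWM(self.id + "_shuf", self.probs[perm],
                   background=self.background,
                   strand_policy=self.strand_policy)

    @classmethod
    def from_iupac(cls, motif_id: str, consensus: str, eps: float = 0.02,
                   strand_policy: str = "sense_only",
                   background: np.ndarray | None = None) -> "PWM":
        """Degenerate consensus string to PWM (eps spread over other bases)."""
        L = len(consensus)
        probs = np.full((L, 4), 0.0)
        for i, c in enumerate(consensus.upper()):
            allowed = IUPAC.get(c)
            if allowed is None:
                raise ValueError(f"invalid IUPAC symbol {c!r}")
            for b in _BASES:
                probs[i, _BASES.index(b)] = ((1 - eps) / len(allowed)
                                             if b in allowed else eps / (4 - len(allowed)))
            if len(allowed) == 4:
                probs[i] = 0.25
        return cls(motif_id, probs, background=background,
                   strand_policy=strand_policy)


# Compact degenerate consensus strings for the canonical Drosophila core
# promoter elements (TATA box, Initiator, DPE, MTE, DRE, the Ohler
# intermediate-class elements and the TCT ribosomal-protein initiator).
# These are deliberately short approximations suitable for scanning and for
# exact-null computations; users can substitute JASPAR/MEME files.
CORE_MOTIF_CONSENSUS: dict[str, str] = {
    "TATA": "STATAAA",
    "INR": "TCAGTY",
    "DPE": "KCGGTTSK",
    "MTE": "CSARCSSA",
    "DRE": "TATCGATA",
    "Ohler1": "YGGTCACA",
    "Ohler5": "RGTATWTT",
    "Ohler6": "CAKCNCTR",
    "Ohler7": "CAGCTGWY",
    "TCT": "YYCTTTYY",
}


def core_promoter_pwms(eps: float = 0.02) -> list[PWM]:
    """The bundled minimal core-promoter PWM set (sense-strand scanning)."""
    return [PWM.from_iupac(name, cons, eps=eps)
            for name, cons in CORE_MOTIF_CONSENSUS.items()]


# ---------------------------------------------------------------------------
# scanning and exact null distribution


def score_threshold(pwm: PWM, pvalue: float, scale: int = 1000) -> float:
    """Log-odds threshold achieving tail probability <= ``pvalue``.

    The exact distribution of the per-offset score under the i.i.d.
    background null is computed by dynamic programming over positions with
    scores discretized to ``1/scale`` bits.  Returns the smallest score s
    with P(score >= s) <= pvalue.
    """
    if not 0 < pvalue <= 1:
        raise ValueError("pvalue must be in (0, 1]")
    lo = np.round(pwm.log_odds[:, :4] * scale).astype(np.int64)
    # DP over positions on a dense integer score grid
    dist = np.array([1.0])
    base = 0  # integer score of dist[0]
    for i in range(len(pwm)):
        row = lo[i]
        lo_i, hi_i = int(row.min()), int(row.max())
        new = np.zeros(dist.size + hi_i - lo_i)
        for b in range(4):
            shift = int(row[b]) - lo_i
            new[shift:shift + dist.size] += pwm.background[b] * dist
        dist = new
        base += lo_i
    tail = np.cumsum(dist[::-1])[::-1]
    idx = int(np.searchsorted(-tail, -pvalue, side="left"))
    # report the smallest *achievable* score with tail probability <= pvalue
    achievable = np.flatnonzero(dist[idx:] > 0)
    idx = idx + int(achievable[0]) if achievable.size else dist.size - 1
    return (base + idx) / scale


@dataclass
class MotifHit:
    """Best match of one motif in one promoter window."""

    motif_id: str
    tsc_id: str | None
    score: float
    offset: int       # motif start relative to the main TSS
    strand: str       # '+' sense, '-' antisense (both-strand policy only)
    present: bool


def _best_score(codes: np.ndarray, lo: np.ndarray) -> tuple[float, int]:
    L = lo.shape[0]
    n_off = codes.size - L + 1
    if n_off <= 0:
        raise ValueError("window shorter than the motif")
    idx = codes[np.arange(n_off)[:, None] + np.arange(L)[None, :]]
    scores = lo[np.arange(L)[None, :], idx].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), best


def pwm_scan(window: str, pwm: PWM, threshold: float | None = None,
             pvalue: float | None = None, tss_index: int | None = None,
             tsc_id: str | None = None) -> MotifHit:
    """Best-scoring match of a PWM in a promoter window.

    ``window`` is strand-oriented (promoter sense); ``tss_index`` locates the
    main TSS inside it (defaults to the center).  Scores are summed log2
    odds; non-ACGT bases contribute 0.  The hit is ``present`` when the best
    score reaches ``threshold`` (given directly, or derived from ``pvalue``
    via the exact background null).
    """
    if tss_index is None:
        tss_index = len(window) // 2
    if threshold is None:
        threshold = score_threshold(pwm, pvalue) if pvalue is not None else None
    codes = _encode(window)
    score, off = _best_score(codes, pwm.log_odds)
    strand = "+"
    if pwm.strand_policy == "both":
        rc = pwm.reverse_complement()
        score_rc, off_rc = _best_score(codes, rc.log_odds)
        if score_rc > score:
            score, off, strand = score_rc, off_rc, "-"
    return MotifHit(motif_id=pwm.id, tsc_id=tsc_id, score=score,
                    offset=off - tss_index, strand=strand,
                    present=bool(threshold is not None and score >= threshold))


def scan_promoters(windows: dict[str, str], pwms: list[PWM],
                   pvalue: float = 1e-3,
                   thresholds: dict[str, float] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan many promoter windows with many PWMs.

    Returns ``(scores, presence)`` DataFrames indexed by promoter id with
    one column per motif.  Per-motif thresholds default to the exact-null
    p-value criterion.
    """
    ids = list(windows)
    scores = pd.DataFrame(index=ids, columns=[p.id for p in pwms], dtype=float)
    presence = pd.DataFrame(False, index=ids, columns=[p.id for p in pwms])
    for pwm in pwms:
        thr = (thresholds or {}).get(pwm.id)
        if thr is None:
            thr = score_threshold(pwm, pvalue)
        for tid, win in windows.items():
            hit = pwm_scan(win, pwm, threshold=thr, tsc_id=tid)
            scores.loc[tid, pwm.id] = hit.score
            presence.loc[tid, pwm.id] = hit.present
    return scores, presence


# ---------------------------------------------------------------------------
# enrichment statistics


def enrichment(presence: pd.DataFrame, groups: pd.Series,
               cap: float = np.inf) -> pd.DataFrame:
    """Per-(motif, group) enrichment with FDR-corrected chi-square tests.

    For each motif and group, a 2x2 table of presence inside vs. outside the
    group gives a chi-square p-value (Fisher's exact test when an expected
    cell count drops below 5, flagged in the ``test`` column) and two
    ratios: ``ratio_vs_rest`` (group frequency over the frequency in all
    other groups, the displayed enrichment) and ``ratio_vs_overall`` (over
    the pooled frequency, whose group-size-weighted mean is exactly 1).
    Benjamini-Hochberg correction runs across all (motif, group) tests.
    """
    groups = groups.reindex(presence.index)
    if groups.isna().any():
        raise ValueError("every promoter needs a group label")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for motif in presence.columns:
        pres = presence[motif].astype(bool)
        overall = pres.mean()
        for g in levels:
            ing = groups == g
            a = int((pres & ing).sum())      # present, in group
            b = int((~pres & ing).sum())
            c = int((pres & ~ing).sum())
            d = int((~pres & ~ing).sum())
            table = np.array([[a, b], [c, d]])
            freq_in = a / max(a + b, 1)
            freq_out = c / max(c + d, 1)
            ratio = np.inf if freq_out == 0 and freq_in > 0 else (
                freq_in / freq_out if freq_out > 0 else np.nan)
            if np.isinf(ratio):
                ratio = cap
            expected = stats.contingency.expected_freq(table) \
                if table.sum() else np.zeros((2, 2))
            if table.sum() and expected.min() >= 5:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                test = "chi2"
            else:
                _, p = stats.fisher_exact(table)
                test = "fisher"
            rows.append({"motif": motif, "group": g, "n_group": int(ing.sum()),
                         "freq_in_group": freq_in, "freq_rest": freq_out,
                         "ratio_vs_rest": ratio,
                         "ratio_vs_overall": (freq_in / overall
                                              if overall > 0 else np.nan),
                         "p_value": p, "test": test})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def cooccurrence_clusters(presence: pd.DataFrame, n_groups: int = 3,
                          method: str = "complete"
                          ) -> tuple[pd.Series, list[str]]:
    """Group motifs by co-occurrence within the same promoters.

    Pairwise motif distance is 1 minus the phi coefficient of the 2x2
    presence table (phi equals the Pearson correlation of the indicator
    vectors).  The linkage tree is cut into ``n_groups``.  Motifs present in
    none or all promoters have an undefined phi and are excluded (returned
    in the second element).
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least 2 motifs")
    X = presence.astype(float)
    var = X.var(axis=0)
    excluded = list(X.columns[var == 0])
    if excluded:
        logger.info("excluding constant motifs from co-occurrence: %s", excluded)
    X = X.loc[:, var > 0]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant motifs")
    phi = np.corrcoef(X.values.T)
    D = 1.0 - phi
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=min(n_groups, X.shape[1]), criterion="maxclust")
    return pd.Series(labels, index=X.columns, name="group"), excluded


# ---------------------------------------------------------------------------
# QDA phase classifier


class GaussianQDA:
    """Quadratic discriminant analysis with per-class ridge regularization.

    Each class gets its own Gaussian (mean and full covariance); a ridge
    term ``lam`` is added to the covariance diagonal for stability, with the
    default ``lam = 1e-3 * trace / d`` per class.
    """

    def __init__(self, ridge: float | str = "auto"):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        d = X.shape[1]
        self.means_, self._prec, self._logdet, self.priors_ = [], [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] < d + 2:
                raise ValueError(
                    f"class {c!r} has {Xc.shape[0]} members; need at least "
                    f"n_features + 2 = {d + 2}")
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False)
            cov = np.atleast_2d(cov)
            lam = (1e-3 * np.trace(cov) / d if self.ridge == "auto"
                   else float(self.ridge))
            cov = cov + lam * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "class covariance is singular even after ridge "
                    "regularization; increase the ridge parameter") from exc
            self.means_.append(mu)
            self._prec.append(np.linalg.inv(cov))
            self._logdet.append(2 * np.log(np.diag(chol)).sum())
            self.priors_.append(Xc.shape[0] / X.shape[0])
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff = X - self.means_[k]
            maha = np.einsum("ij,jk,ik->i", diff, self._prec[k], diff)
            out[:, k] = -0.5 * (maha + self._logdet[k]) + np.log(self.priors_[k])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_posterior(X)
        return self.classes_[np.argmax(lp, axis=1)]


def log_transform_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """``log(score - global_min + 1)`` feature transform (log-odds can be < 0)."""
    return np.log(scores - scores.values.min() + 1.0)


@dataclass
class QDAPhaseResult:
    predictions: pd.Series
    confusion: pd.DataFrame
    accuracy: float
    per_class_p: pd.Series
    per_class_q: pd.Series


def qda_phase_classifier(scores: pd.DataFrame, phases: pd.Series,
                         ridge: float | str = "auto") -> QDAPhaseResult:
    """Predict developmental phase from motif scores; assess by LOOCV.

    Features are log-transformed motif log-odds scores.  The leave-one-out
    confusion matrix is compared to chance per true class with chi-square
    goodness-of-fit tests (uniform expectation), FDR-corrected.
    """
    phases = phases.reindex(scores.index)
    if phases.isna().any():
        raise ValueError("every promoter needs a phase label")
    X = log_transform_scores(scores).values
    y = phases.values
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    for i in range(n):
        sel = np.ones(n, dtype=bool)
        sel[i] = False
        model = GaussianQDA(ridge=ridge).fit(X[sel], y[sel])
        preds[i] = model.predict(X[i:i + 1])[0]
    predictions = pd.Series(preds, index=scores.index, name="predicted")
    confusion = pd.crosstab(phases, predictions, dropna=False)
    classes = sorted(set(y))
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    accuracy = float((preds == y).mean())
    pvals = {}
    for c in classes:
        obs = confusion.loc[c].values
        if obs.sum() == 0:
            pvals[c] = np.nan
            continue
        pvals[c] = stats.chisquare(obs).pvalue
    per_class_p = pd.Series(pvals)
    ok = per_class_p.notna()
    q = pd.Series(np.nan, index=per_class_p.index)
    if ok.any():
        q[ok] = multipletests(per_class_p[ok], method="fdr_bh")[1]
    return QDAPhaseResult(predictions, confusion, accuracy, per_class_p, q)


# ---------------------------------------------------------------------------
# motif functional conservation


def motif_functional_conservation(ref_windows: dict[str, str],
                                  target_windows: dict[str, str],
                                  pwms: list[PWM], pvalue: float = 1e-3,
                                  shuffles: int = 10, seed: int = 0
                                  ) -> pd.DataFrame:
    """Cross-species conservation of motif presence vs. a shuffled baseline.

    Both window dicts are keyed by the same promoter ids (functionally
    conserved promoters whose main TSS projects across genomes).  For each
    motif: the conservation rate is the fraction of reference-present
    promoters also present in the orthologous target window; the baseline
    repeats this with column-shuffled PWMs (position multiset preserved;
    the null score distribution, hence the threshold, is unchanged by the
    permutation).  A chi-square test compares real vs. shuffled conserved
    counts, Benjamini-Hochberg corrected across motifs.
    """
    shared = [k for k in ref_windows if k in target_windows]
    if not shared:
        raise ValueError("no promoters with projectable windows in both species")
    rng = np.random.default_rng(seed)
    rows = []
    for pwm in pwms:
        thr = score_threshold(pwm, pvalue)
        ref_present = [k for k in shared
                       if pwm_scan(ref_windows[k], pwm, threshold=thr).present]
        n_ref = len(ref_present)
        n_cons = sum(pwm_scan(target_windows[k], pwm, threshold=thr).present
                     for k in ref_present)
        shuf_ref = shuf_cons = 0
        for _ in range(shuffles):
            spwm = pwm.shuffled(rng)
            pres = [k for k in shared
                    if pwm_scan(ref_windows[k], spwm, threshold=thr).present]
            shuf_ref += len(pres)
            shuf_cons += sum(pwm_scan(target_windows[k], spwm,
                                      threshold=thr).present for k in pres)
        rate = n_cons / n_ref if n_ref else np.nan
        shuf_rate = shuf_cons / shuf_ref if shuf_ref else np.nan
        table = np.array([[n_cons, n_ref - n_cons],
                          [shuf_cons, shuf_ref - shuf_cons]])
        if table.sum() and (table.sum(axis=1) > 0).all():
            expected = stats.contingency.expected_freq(table)
            if expected.min() >= 5:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            else:
                _, p = stats.fisher_exact(table)
        else:
            p = np.nan
        rows.append({"motif": pwm.id, "n_ref_present": n_ref,
                     "n_conserved": n_cons, "rate": rate,
                     "shuffled_rate": shuf_rate, "p_value": p})
    df = pd.DataFrame(rows).set_index("motif")
    ok = df["p_value"].notna()
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = multipletests(df.loc[ok, "p_value"],
                                              method="fdr_bh")[1]
    return df


def iupac_find(pattern: str, seq: str) -> list[int]:
    """Offsets of exact degenerate-consensus matches (sense strand)."""
    pat = [set(IUPAC[c]) for c in pattern.upper()]
    s = seq.upper()
    hits = []
    for i in range(len(s) - len(pat) + 1):
        if all(s[i + j] in pat[j] for j in range(len(pat))):
            hits.append(i)
    return hits
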