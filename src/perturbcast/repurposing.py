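"""Signature-reversal compound screening.

A patient's disease signature (sets of up- and down-regulated genes) is
compared against each drug-induced expression profile with an equal-weight
enrichment statistic: for a ranked profile L of m genes and a query set Gq
of n_q genes, the running statistic at query gene i is

    D_q(i) = (#{j in L: g_j < g_i}) / m  -  (#{j in Gq: g_j < g_i}) / n_q,

(strict inequalities; ties contribute nothing), and the enrichment score
ES_q is whichever of sup/inf over i in Gq has the larger magnitude. A drug
that pushes the patient's up-genes down and down-genes up earns enrichment
scores of opposite signs; the reverse-similarity score is then
S = -(ES_up + ES_down), and 0 when the signs agree.

Significance comes from a permutation null: enrichment statistics of
randomly drawn gene groups are histogrammed into 2,000 equal bins on
[-1, 1], the histogram is smoothed locally with the model exp(a + bx + cx^2),
and the p-value of a score x is the integral of the smoothed density from x
to 1. The null statistic is configurable: the continuous single-set
enrichment score (the calibrated choice), or the reverse-similarity score of
random disjoint set pairs (which carries a point mass at 0 from same-sign
pairs and is therefore conservative; its ties are resolved by ranking on S).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import is_safe

logger = logging.getLogger(__name__)

N_BINS = 2000
SMOOTH_WINDOW = 0.015
MIN_SIGNATURE_GENES = 10


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class PatientSignature:
    patient_id: str
    up_genes: set
    down_genes: set

    def __post_init__(self):
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets overlap")

    @property
    def eligible(self) -> bool:
        return len(self.up_genes) + len(self.down_genes) >= MIN_SIGNATURE_GENES


@dataclass
class RankedProfile:
    """A drug-induced profile used as the ranked gene list L."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("one value per gene required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        # strict rank: number of profile values strictly below each value
        order = np.sort(self.values)
        self._lt_count = np.searchsorted(order, self.values, side="left")

    @property
    def m(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentScores:
    es_up: float
    es_down: float


@dataclass
class NullDistribution:
    bin_edges: np.ndarray       # length N_BINS + 1, spanning [-1, 1]
    counts: np.ndarray          # raw histogram counts, sum == n_perms
    n_perms: int
    statistic: str
    density: np.ndarray | None = None  # smoothed, integrates to 1

    def __post_init__(self):
        if int(self.counts.sum()) != self.n_perms:
            raise ValueError("histogram counts must sum to n_perms")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ScreenResult:
    drug_id: str
    patient_id: str
    es_up: float
    es_down: float
    score: float
    p_value: float
    safe: bool
    candidate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# Enrichment statistic
# ---------------------------------------------------------------------------

def enrichment_score(profile: RankedProfile, query: set) -> float:
    """Equal-weight enrichment score of a query gene set in a ranked profile."""
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    missing = sorted(g for g in query if g not in profile._index)
    if missing:
        raise ValueError(f"query genes absent from profile: {missing}")
    idx = np.array([profile._index[g] for g in query])
    vals = profile.values[idx]
    n_q = len(idx)
    order = np.sort(vals)
    local_lt = np.searchsorted(order, vals, side="left")
    d = profile._lt_count[idx] / profile.m - local_lt / n_q
    es_sup = float(d.max())
    es_inf = float(d.min())
    return es_sup if abs(es_sup) >= abs(es_inf) else es_inf


def reverse_similarity(es_up: float, es_down: float) -> float:
    """-(ES_up + ES_down) when the scores have opposite signs, else 0."""
    for es in (es_up, es_down):
        if abs(es) > 1:
            raise ValueError("enrichment scores must lie in [-1, 1]")
    if es_up * es_down < 0:
        return -(es_up + es_down)
    return 0.0


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def _draw_pair(rng: np.random.Generator, m: int, n_up: int, n_down: int):
    pick = rng.choice(m, size=n_up + n_down, replace=False)
    return pick[:n_up], pick[n_up:]


def _es_from_indices(profile: RankedProfile, idx: np.ndarray) -> float:
    vals = profile.values[idx]
    order = np.sort(vals)
    local_lt = np.searchsorted(order, vals, side="left")
    d = profile._lt_count[idx] / profile.m - local_lt / len(idx)
    es_sup, es_inf = float(d.max()), float(d.min())
    return es_sup if abs(es_sup) >= abs(es_inf) else es_inf


def build_null(profile: RankedProfile, n_up: int, n_down: int,
               n_perms: int = 100_000, rng_seed: int = 0,
               statistic: str = "reverse_similarity",
               smooth: bool = True) -> NullDistribution:
    """Histogram a permutation null of the screening statistic.

    ``statistic="reverse_similarity"``: each permutation draws disjoint
    random up/down sets of the signature's sizes and scores S.
    ``statistic="es"``: each permutation draws a single random set of size
    ``n_up`` (pass ``n_down=0``) and records its enrichment score.
    """
    m = profile.m
    if n_up + n_down > m:
        raise ValueError(f"set sizes {n_up}+{n_down} exceed profile size {m}")
    if n_up < 1:
        raise ValueError("n_up must be >= 1")
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_perms)
    if statistic == "reverse_similarity":
        if n_down < 1:
            raise ValueError("reverse_similarity null needs n_down >= 1")
        for i in range(n_perms):
            up, down = _draw_pair(rng, m, n_up, n_down)
            scores[i] = reverse_similarity(_es_from_indices(profile, up),
                                           _es_from_indices(profile, down))
    elif statistic == "es":
        for i in range(n_perms):
            idx = rng.choice(m, size=n_up, replace=False)
            scores[i] = _es_from_indices(profile, idx)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    edges = np.linspace(-1.0, 1.0, N_BINS + 1)
    counts, _ = np.histogram(np.clip(scores, -1.0, 1.0), bins=edges)
    nd = NullDistribution(bin_edges=edges, counts=counts.astype(float),
                          n_perms=n_perms, statistic=statistic)
    return smooth_null(nd) if smooth else nd


def smooth_null(nd: NullDistribution, window: float = SMOOTH_WINDOW) -> NullDistribution:
    """Locally fit exp(a + bx + cx^2) around each bin and renormalize.

    Each bin's smoothed value is the fit evaluated at the bin center, by
    log-linear least squares on the positive-count bins inside the window
    (empty bins carry no information about the local level of a spiky
    histogram and are excluded). Windows with fewer than three positive
    bins fall back to their mean positive level; windows with none smooth
    to zero. The result is renormalized to integrate to 1.
    """
    width = nd.bin_width
    if window < width:
        raise ValueError(f"window {window} is narrower than one bin ({width})")
    half_bins = max(1, int(round((window / 2.0) / width)))
    centers = nd.bin_centers
    counts = nd.counts
    n = len(counts)
    smoothed = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - half_bins), min(n, i + half_bins + 1)
        mask = counts[lo:hi] > 0
        if not mask.any():
            continue
        x = (centers[lo:hi] - centers[i])[mask]  # centered for conditioning
        y = np.log(counts[lo:hi][mask])
        if mask.sum() < 3:
            smoothed[i] = math.exp(float(y.mean()))
            continue
        design = np.column_stack([np.ones_like(x), x, x * x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        smoothed[i] = math.exp(coef[0])
    total = smoothed.sum() * width
    if total <= 0:
        raise ValueError("smoothed null has zero mass")
    return NullDistribution(bin_edges=nd.bin_edges, counts=nd.counts,
                            n_perms=nd.n_perms, statistic=nd.statistic,
                            density=smoothed / total)


def p_value(score: float, nd: NullDistribution) -> float:
    """Upper-tail integral of the smoothed density from ``score`` to 1."""
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [-1, 1]")
    if nd.density is None:
        raise ValueError("null distribution has not been smoothed")
    width = nd.bin_width
    idx = min(int((score - (-1.0)) / width), N_BINS - 1)
    # full bins above idx plus the partial remainder of bin idx
    tail = nd.density[idx + 1:].sum() * width
    partial = nd.density[idx] * (nd.bin_edges[idx + 1] - score)
    floor = 1.0 / (nd.n_perms + 1)
    return float(min(1.0, max(floor, tail + partial)))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def screen_patient(sig: PatientSignature,
                   drug_profiles: dict[str, RankedProfile],
                   viability: dict[str, object] | None = None,
                   alpha: float = 1e-3,
                   n_perms: int = 10_000,
                   rng_seed: int = 0,
                   null_statistic: str = "reverse_similarity"
                   ) -> list[ScreenResult]:
    """Score and rank a drug library against one patient signature.

    Per drug: enrichment scores of the signature's up and down sets in the
    drug profile, the reverse-similarity score S, and a permutation p-value
    from that drug's profile-specific null. Drugs failing the toxicity
    filter are never candidates but stay in the output. Results are ranked
    by ascending p, then descending S, then drug id.
    """
    results: list[ScreenResult] = []
    # the null depends on the profile only through its strict-rank pattern;
    # tie-free profiles of equal length share one null
    null_cache: dict[tuple, NullDistribution] = {}
    for drug_id in sorted(drug_profiles):
        profile = drug_profiles[drug_id]
        up = {g for g in sig.up_genes if g in profile._index}
        down = {g for g in sig.down_genes if g in profile._index}
        n_dropped = len(sig.up_genes) + len(sig.down_genes) - len(up) - len(down)
        if n_dropped:
            logger.warning("patient %s: %d signature genes absent from panel",
                           sig.patient_id, n_dropped)
        if len(up) + len(down) < MIN_SIGNATURE_GENES:
            logger.info("patient %s skipped: <%d usable signature genes",
                        sig.patient_id, MIN_SIGNATURE_GENES)
            return []
        es_up = enrichment_score(profile, up)
        es_down = enrichment_score(profile, down)
        s = reverse_similarity(es_up, es_down)
        tie_free = len(np.unique(profile.values)) == profile.m
        key = (profile.m, len(up), len(down)) if tie_free else (drug_id,)
        if key not in null_cache:
            null_cache[key] = build_null(profile, len(up), len(down),
                                         n_perms=n_perms, rng_seed=rng_seed,
                                         statistic=null_statistic)
        p = p_value(s, null_cache[key])
        safe = True
        if viability is not None and drug_id in viability:
            safe = is_safe(viability[drug_id])
        results.append(ScreenResult(drug_id=drug_id, patient_id=sig.patient_id,
                                    es_up=es_up, es_down=es_down, score=s,
                                    p_value=p, safe=safe))
    results.sort(key=lambda r: (r.p_value, -r.score, r.drug_id))
    for r in results:
        r.candidate = bool(r.safe and r.p_value < alpha)
    return results


# ---------------------------------------------------------------------------
# Patient clustering (flat-kernel mean shift, Manhattan distance)
# ---------------------------------------------------------------------------

def _signature_vectors(sigs: list[PatientSignature], gene_ids: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(gene_ids)}
    x = np.zeros((len(sigs), len(gene_ids)))
    for i, s in enumerate(sigs):
        for g in s.up_genes:
            if g in index:
                x[i, index[g]] = 1.0
        for g in s.down_genes:
            if g in index:
                x[i, index[g]] = -1.0
    return x


def cluster_patients(sigs: list[PatientSignature], gene_ids: list[str],
                     bandwidth: float | None = None, max_iter: int = 300
                     ) -> dict[str, int]:
    """Mean-shift on +1/-1/0 signature vectors with Manhattan distance.

    Each patient seeds a mode; a flat kernel of the given L1 ``bandwidth``
    (default: half the median pairwise L1 distance, which keeps well-separated
    signature groups apart) shifts seeds to the mean of their in-band
    neighbors until convergence, and modes closer than the bandwidth merge.
    """
    if len(sigs) < 2:
        raise ValueError("need at least 2 patients to cluster")
    x = _signature_vectors(sigs, gene_ids)
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    if bandwidth is None:
        off = d[np.triu_indices(len(sigs), k=1)]
        bandwidth = float(np.median(off)) / 2.0
        if bandwidth <= 0:
            bandwidth = 1.0
    modes = x.copy()
    for _ in range(max_iter):
        dist = np.abs(modes[:, None, :] - x[None, :, :]).sum(axis=2)
        within = dist <= bandwidth
        new_modes = np.stack([x[w].mean(axis=0) if w.any() else modes[i]
                              for i, w in enumerate(within)])
        if np.abs(new_modes - modes).max() < 1e-9:
            modes = new_modes
            break
        modes = new_modes
    labels: list[int] = []
    exemplars: list[np.ndarray] = []
    for mode in modes:
        for ci, ex in enumerate(exemplars):
            if np.abs(mode - ex).sum() <= bandwidth:
                labels.append(ci)
                break
        else:
            exemplars.append(mode)
            labels.append(len(exemplars) - 1)
    return {s.patient_id: int(l) for s, l in zip(sigs, labels)}


# ---------------------------------------------------------------------------
# Drug-set enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(candidates: set, universe: set,
                     annotation: dict[str, set]) -> dict[str, float]:
    """Upper-tail hypergeometric p per annotation term.

    For a term annotating K of the N universe drugs, with k hits among the
    n candidates: p = P(X >= k), X ~ Hypergeom(N, K, n).
    """
    candidates = set(candidates)
    universe = set(universe)
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    terms: dict[str, set] = {}
    for drug, anns in annotation.items():
        if drug in universe:
            for t in anns:
                terms.setdefault(t, set()).add(drug)
    out: dict[str, float] = {}
    n_univ, n_cand = len(universe), len(candidates)
    for term, drugs in terms.items():
        big_k = len(drugs)
        if big_k == 0:
            continue
        k = len(drugs & candidates)
        out[term] = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_cand))
    return out
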