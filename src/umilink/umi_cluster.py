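"""UMI extraction and greedy agglomerative clustering of long reads.

Reads are grouped by the similarity of their 50-bp UMI tags.  A full
all-vs-all comparison is quadratic in the number of reads and quickly
becomes infeasible; instead a one-pass greedy scheme is used: the next
unassigned read seeds a cluster and absorbs every unassigned read whose
UMI aligns to the seed's UMI with a Smith–Waterman score at or above the
threshold.  This costs O(k·n) alignments for k clusters.

Alignment scoring is affine-gap local alignment (Gotoh).  With the default
unit scores (match +1, mismatch −1, gap −1 per base) the score is an
edit-like similarity, so thresholds are interpretable in base units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from umilink.seqio import NanoporeRead, reverse_complement


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap local alignment scores and the clustering threshold.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``, so the
    defaults charge one unit per gap base.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -1
    gap_extend: int = -1
    threshold: int = 0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


@dataclass(frozen=True)
class UMIExtraction:
    """Result of locating the UMI in one read via its anchor probe."""

    read_id: str
    umi: str
    anchor_score: float
    ok: bool
    strand: str = "+"
    reason: str = ""


@dataclass
class Cluster:
    """Reads grouped around one seed UMI."""

    cluster_id: str
    seed_umi: str
    member_read_ids: list[str]

    def __len__(self) -> int:
        return len(self.member_read_ids)


# ---------------------------------------------------------------------------
# Numba alignment kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_score(a, b, match, mismatch, gap_open, gap_extend):
    """Smith–Waterman local score with affine gaps (linear memory)."""
    n, m = a.shape[0], b.shape[0]
    NEG = -10**9
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = 0
        F = NEG
        for j in range(1, m + 1):
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)
            F = max(H[j - 1] + gap_open, F + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_locate(a, b, match, mismatch, gap_open, gap_extend):
    """Local alignment score of ``a`` in ``b`` plus the end index on ``b``
    (index one past the last aligned base of ``b``)."""
    n, m = a.shape[0], b.shape[0]
    NEG = -10**9
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    best_j = 0
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = 0
        F = NEG
        for j in range(1, m + 1):
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)
            F = max(H[j - 1] + gap_open, F + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
                best_j = j
    return best, best_j


@njit(cache=True)
def _greedy_assign(codes, lengths, threshold, match, mismatch, gap_open, gap_extend):
    """One-pass greedy clustering on encoded UMIs; returns a label per row."""
    n = codes.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = next_label
        seed = codes[i, : lengths[i]]
        for j in range(i + 1, n):
            if labels[j] >= 0:
                continue
            s = _sw_score(seed, codes[j, : lengths[j]],
                          match, mismatch, gap_open, gap_extend)
            if s >= threshold:
                labels[j] = next_label
        next_label += 1
    return labels


@njit(cache=True)
def _best_seed_assign(codes, lengths, seed_rows, labels,
                      match, mismatch, gap_open, gap_extend):
    """Reassign every row to its best-scoring seed (ties keep the earlier
    seed).  The greedy pass absorbs a read into the first cluster whose seed
    clears the threshold, which can capture reads whose own seed appears
    later; one argmax pass over the discovered seeds repairs that."""
    n = codes.shape[0]
    k = seed_rows.shape[0]
    out = np.empty(n, dtype=np.int64)
    for j in range(n):
        best_label = labels[j]
        best_score = -1
        for s in range(k):
            row = seed_rows[s]
            score = _sw_score(codes[row, : lengths[row]],
                              codes[j, : lengths[j]],
                              match, mismatch, gap_open, gap_extend)
            if score > best_score:
                best_score = score
                best_label = s
        out[j] = best_label
    return out


_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
_ENCODE[ord("a")] = 0
_ENCODE[ord("c")] = 1
_ENCODE[ord("g")] = 2
_ENCODE[ord("t")] = 3


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def umi_score(a: str, b: str, params: Optional[ScoringParams] = None) -> int:
    """Smith–Waterman local alignment score of two sequences (symmetric)."""
    params = params or ScoringParams()
    if not a or not b:
        return 0
    return int(_sw_score(_encode(a), _encode(b), params.match, params.mismatch,
                         params.gap_open, params.gap_extend))


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------

def extract_umi(
    read: NanoporeRead,
    probe: str,
    L: int,
    params: Optional[ScoringParams] = None,
    score_min: Optional[float] = None,
    length_tol: int = 5,
) -> UMIExtraction:
    """Locate the constant probe in a read and return the following L bases.

    The probe is aligned locally against the read and its reverse
    complement; the better strand is chosen, orienting the read so that the
    UMI is read in construct orientation.  Extraction fails when the best
    anchor score falls below ``score_min`` (default 0.7 × match × probe
    length) or fewer than ``L − length_tol`` bases follow the probe.
    """
    params = params or ScoringParams()
    if L < 1:
        raise ValueError("UMI length must be >= 1")
    if len(probe) < 10:
        raise ValueError("probe must be at least 10 bases")
    if score_min is None:
        score_min = 0.7 * params.match * len(probe)
    if len(read.bases) < len(probe) + L:
        return UMIExtraction(read.read_id, "", 0.0, False, reason="too_short")

    probe_codes = _encode(probe)
    best_score = -1
    best_end = 0
    best_strand = "+"
    for strand, seq in (("+", read.bases), ("-", reverse_complement(read.bases))):
        score, end = _sw_locate(probe_codes, _encode(seq), params.match,
                                params.mismatch, params.gap_open, params.gap_extend)
        if score > best_score:
            best_score, best_end, best_strand = int(score), int(end), strand
    if best_score < score_min:
        return UMIExtraction(read.read_id, "", float(best_score), False,
                            reason="no_anchor")
    seq = read.bases if best_strand == "+" else reverse_complement(read.bases)
    umi = seq[best_end : best_end + L]
    if len(umi) < L - length_tol:
        return UMIExtraction(read.read_id, "", float(best_score), False,
                            strand=best_strand, reason="too_short")
    return UMIExtraction(read.read_id, umi, float(best_score), True,
                        strand=best_strand)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pack(umis: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(u) for u in umis], dtype=np.int64)
    codes = np.zeros((len(umis), int(lengths.max(initial=1))), dtype=np.uint8)
    for i, u in enumerate(umis):
        codes[i, : len(u)] = _encode(u)
    return codes, lengths


def cluster_greedy(
    extractions: Sequence[UMIExtraction],
    params: ScoringParams,
    refine: bool = True,
) -> list[Cluster]:
    """Greedy agglomerative clustering of extracted UMIs.

    Iterates over extractions in input order: the next unassigned one seeds
    a new cluster and absorbs every unassigned extraction whose UMI scores
    at least ``params.threshold`` against the seed.  With ``refine`` (the
    default) a second pass then moves every read to its best-scoring seed:
    the one-pass scheme assigns a read to the *first* seed clearing the
    threshold, which occasionally captures reads of a template whose own
    seed only appears later in the input.  Both passes cost O(k·n)
    alignments for k clusters — never all-vs-all.

    The output is a partition of the successfully extracted reads (failed
    extractions must be filtered out by the caller) and is deterministic
    for a given input order.
    """
    ok = [e for e in extractions if e.ok]
    if any(not e.ok for e in extractions):
        raise ValueError("failed extractions must be excluded before clustering")
    if not ok:
        return []
    codes, lengths = _pack([e.umi for e in ok])
    labels = _greedy_assign(codes, lengths, params.threshold, params.match,
                            params.mismatch, params.gap_open, params.gap_extend)
    seed_rows = np.empty(int(labels.max()) + 1, dtype=np.int64)
    for row in range(len(ok) - 1, -1, -1):
        seed_rows[labels[row]] = row  # first row of each label is its seed
    if refine:
        labels = _best_seed_assign(codes, lengths, seed_rows, labels,
                                   params.match, params.mismatch,
                                   params.gap_open, params.gap_extend)
    clusters: dict[int, Cluster] = {}
    for ext, label in zip(ok, labels):
        label = int(label)
        if label not in clusters:
            clusters[label] = Cluster(cluster_id=f"cluster{label:05d}",
                                      seed_umi=ok[seed_rows[label]].umi,
                                      member_read_ids=[])
        clusters[label].member_read_ids.append(ext.read_id)
    return [clusters[k] for k in sorted(clusters)]


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

@dataclass
class ThresholdEstimate:
    """Chosen clustering threshold plus diagnostics."""

    threshold: int
    cluster_counts: dict[int, int]
    self_scores: list[int] = field(default_factory=list)
    cross_scores: list[int] = field(default_factory=list)


def _greedy_from_matrix(scores: np.ndarray, threshold: int) -> int:
    """Cluster count of the greedy pass given a precomputed score matrix."""
    n = scores.shape[0]
    unassigned = np.ones(n, dtype=bool)
    n_clusters = 0
    for i in range(n):
        if not unassigned[i]:
            continue
        members = unassigned & (scores[i] >= threshold)
        members[i] = True
        unassigned &= ~members
        n_clusters += 1
    return n_clusters


def estimate_threshold(
    umis: Sequence[str],
    thresholds: Sequence[int],
    params: Optional[ScoringParams] = None,
    sample_size: int = 500,
    reerror_rate: float = 0.1,
    seed: int = 0,
    plateau_tol: float = 0.05,
    min_plateau: int = 3,
) -> ThresholdEstimate:
    """Pick a clustering threshold from the cluster-count plateau.

    A subsample of UMIs is clustered at every candidate threshold.  Between
    the regime where distinct templates merge (low threshold) and the regime
    where copies of one template split (high threshold) the cluster count is
    stable; the midpoint of the widest such plateau (longest run of
    consecutive thresholds whose count changes by less than ``plateau_tol``)
    is returned.  For diagnostics, score distributions of simulated
    same-template pairs (each UMI re-erred twice at ``reerror_rate``) and of
    random cross pairs are reported.

    Raises ``ValueError`` ("no stable threshold") when no plateau of at
    least ``min_plateau`` thresholds exists — typically a sign that the UMIs
    are too short for the error rate.
    """
    from umilink.simulate import ErrorModel, apply_read_errors

    if len(umis) < 200:
        raise ValueError("need a sample of at least 200 UMIs")
    params = params or ScoringParams()
    rng = np.random.default_rng(seed)
    sample = list(umis)
    if len(sample) > sample_size:
        idx = rng.choice(len(sample), size=sample_size, replace=False)
        sample = [sample[i] for i in sorted(idx)]
    n = len(sample)
    codes, lengths = _pack(sample)
    scores = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            s = _sw_score(codes[i, : lengths[i]], codes[j, : lengths[j]],
                          params.match, params.mismatch,
                          params.gap_open, params.gap_extend)
            scores[i, j] = scores[j, i] = s

    counts = {int(t): _greedy_from_matrix(scores, int(t)) for t in thresholds}
    # Exclude the two trivially stable saturation regimes: everything merged
    # into one cluster (too low) and (almost) everything a singleton (too
    # high).  Only the informative region in between can hold the plateau.
    ts = [t for t in sorted(counts) if 1 < counts[t] < 0.9 * n]
    # longest run of consecutive thresholds with <plateau_tol relative change
    best_run: tuple[int, int] = (0, 0)  # (start index, length)
    run_start = 0
    for k in range(1, len(ts) + 1):
        end_of_run = k == len(ts)
        if not end_of_run:
            prev, cur = counts[ts[k - 1]], counts[ts[k]]
            stable = (ts[k] - ts[k - 1] == 1
                      and abs(cur - prev) < plateau_tol * max(prev, 1))
        if end_of_run or not stable:
            length = k - run_start
            if length > best_run[1]:
                best_run = (run_start, length)
            run_start = k
    if best_run[1] < min_plateau:
        raise ValueError(
            "no stable threshold: no cluster-count plateau found; "
            "consider longer UMIs or a wider threshold range"
        )
    # within the widest plateau, prefer the midpoint of its longest
    # strictly-constant stretch (the <tol criterion allows a slow drift
    # that would otherwise bias the midpoint)
    run = ts[best_run[0] : best_run[0] + best_run[1]]
    flat_best = (0, 1)
    flat_start = 0
    for k in range(1, len(run) + 1):
        if k == len(run) or counts[run[k]] != counts[run[flat_start]]:
            if k - flat_start > flat_best[1]:
                flat_best = (flat_start, k - flat_start)
            flat_start = k
    chosen = run[flat_best[0] + flat_best[1] // 2]

    model = ErrorModel.from_total(reerror_rate, seed=seed)
    self_scores = []
    cross_scores = []
    for _ in range(min(200, n)):
        u = sample[int(rng.integers(0, n))]
        a = apply_read_errors(u, model, rng)
        b = apply_read_errors(u, model, rng)
        self_scores.append(umi_score(a, b, params))
        i, j = rng.integers(0, n, size=2)
        if i == j:
            j = (j + 1) % n
        cross_scores.append(int(scores[int(i), int(j)]))
    return ThresholdEstimate(threshold=int(chosen), cluster_counts=counts,
                             self_scores=self_scores, cross_scores=cross_scores)
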