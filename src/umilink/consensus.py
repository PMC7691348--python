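"""Per-cluster consensus variant calling against the parental reference.

Each UMI cluster's reads are aligned end-gap-free to the reference gene and
collapsed into a per-position pileup.  Calling is two-stage:

1. a column-wise majority consensus sequence is built from the pileup and
   diffed once against the reference with a substitution-preferring global
   alignment.  Per-read edit paths are ambiguous exactly where it hurts —
   adjacent substitutions are representable as a deletion plus an
   insertion, and a substitution extending a homopolymer trades off against
   a deletion in it — so candidate mutations are derived from the single
   consensus hypothesis, not by majority vote over per-read edit
   operations;
2. each candidate's support fraction is then measured per read by local
   re-alignment: a read supports the candidate when its bases over a small
   window around the locus sit closer (by edit distance) to the mutated
   reference than to the reference itself.

A candidate passes when its support exceeds ``min_support`` (default 0.6,
strict) and, when both strands are sufficiently represented, when each
strand individually supports it — the strand filter depletes systematic
errors that occur predominantly in one read direction.  Whole variants
carrying more than ``max_mutations`` passed calls (default 16) are
discarded as likely artefacts.

Read-to-reference alignment is base-space edit-distance alignment (edlib,
infix mode: the full reference must align, read overhangs are free).
Signal-level polishing is not used anywhere in this package; the support
fraction is always the fraction of a cluster's position-overlapping reads
that carry the candidate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
from numba import njit

from umilink.seqio import (
    MutationCall,
    NanoporeRead,
    ReferenceGene,
    left_align_indel,
    reverse_complement,
)
from umilink.umi_cluster import Cluster, ScoringParams

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class FilterParams:
    """The consensus quality filters.

    ``min_support``: strict lower bound on the read support fraction of a
    passing call (a call supported by exactly this fraction fails).
    ``max_mutations``: variants with more passed calls than this are
    discarded wholesale.  ``min_strand_support`` is applied on each strand
    separately whenever both strands contribute at least
    ``min_strand_reads`` reads.
    """

    min_support: float = 0.6
    max_mutations: int = 16
    min_strand_support: float = 0.3
    min_strand_reads: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if self.max_mutations < 0:
            raise ValueError("max_mutations must be >= 0")


@dataclass
class ReadAlignment:
    """Semi-global alignment of one read against the reference."""

    read_id: str
    strand: str  # orientation of the read relative to the reference
    offset: int  # start of the aligned region on the read
    cigar: list[tuple[int, str]]  # (length, op) with ops =, X, I(del in read), D(ins in read)
    score: int
    ok: bool
    reason: str = ""


def _score_from_cigar(cigar: list[tuple[int, str]], params: ScoringParams) -> int:
    score = 0
    for length, op in cigar:
        if op == "=":
            score += length * params.match
        elif op == "X":
            score += length * params.mismatch
        else:
            score += params.gap_open + (length - 1) * params.gap_extend
    return score


def align_semi_global(
    read: NanoporeRead,
    ref: ReferenceGene,
    params: Optional[ScoringParams] = None,
    score_floor_frac: float = 0.3,
) -> ReadAlignment:
    """Align a read to the reference, end-gap-free on the read.

    The read is tried in both orientations and the one with the smaller
    edit distance wins (ties keep the forward orientation).  The resulting
    edit path is scored with ``params``; alignments scoring below
    ``score_floor_frac × match × len(ref)`` are rejected so that junk reads
    never enter the pileup.
    """
    params = params or ScoringParams()
    best = None
    for strand, seq in (("+", read.bases), ("-", reverse_complement(read.bases))):
        res = edlib.align(ref.nt_sequence, seq, mode="HW", task="distance")
        if best is None or res["editDistance"] < best[1]:
            best = (strand, res["editDistance"], seq)
    strand, _, seq = best
    res = edlib.align(ref.nt_sequence, seq, mode="HW", task="path")
    cigar = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    score = _score_from_cigar(cigar, params)
    offset = res["locations"][0][0]
    floor = score_floor_frac * params.match * len(ref.nt_sequence)
    if score < floor:
        return ReadAlignment(read.read_id, strand, offset, cigar, score,
                             ok=False, reason="below_score_floor")
    return ReadAlignment(read.read_id, strand, offset, cigar, score, ok=True)


def _walk_alignment(aln: ReadAlignment, read_seq: str, ref_seq: str):
    """Yield raw edit events from one alignment as (kind, pos, ref, alt).

    Positions are left-aligned.  Runs of I/D in the edit path are emitted as
    single multi-base deletion/insertion events.  These per-read events feed
    the pileup; final candidates come from the consensus diff instead.
    """
    qpos = 0  # reference position
    tpos = aln.offset  # read position
    seq = read_seq
    for length, op in aln.cigar:
        if op == "=":
            qpos += length
            tpos += length
        elif op == "X":
            for k in range(length):
                yield ("substitution", qpos + k, ref_seq[qpos + k], seq[tpos + k])
            qpos += length
            tpos += length
        elif op == "I":  # bases of the reference absent from the read: deletion
            pos, ref_a, _ = left_align_indel(qpos, ref_seq[qpos : qpos + length], "", ref_seq)
            yield ("deletion", pos, ref_a, "")
            qpos += length
        elif op == "D":  # extra read bases: insertion before qpos
            ins = seq[tpos : tpos + length]
            pos, _, alt_a = left_align_indel(qpos, "", ins, ref_seq)
            yield ("insertion", pos, "", alt_a)
            tpos += length


def _ref_to_read_map(aln: ReadAlignment) -> np.ndarray:
    """Read coordinate of each reference position (length len(ref)+1)."""
    total_ref = sum(n for n, op in aln.cigar if op in "=XI")
    out = np.empty(total_ref + 1, dtype=np.int64)
    qpos = 0
    tpos = aln.offset
    for length, op in aln.cigar:
        if op in "=X":
            out[qpos : qpos + length] = tpos + np.arange(length)
            qpos += length
            tpos += length
        elif op == "I":
            out[qpos : qpos + length] = tpos
            qpos += length
        else:  # D
            tpos += length
    out[qpos] = tpos
    return out


# ---------------------------------------------------------------------------
# Substitution-preferring global diff (consensus vs reference)
# ---------------------------------------------------------------------------

# Scores chosen so that one substitution (−1) always beats the equivalent
# deletion-plus-insertion representation (−6): per-read edit-distance paths
# are ambiguous on adjacent substitutions and on substitutions that extend a
# homopolymer, and this diff resolves the ambiguity in favour of the
# representation an error-prone-PCR library actually produces.
_DIFF_MATCH = 2
_DIFF_MISMATCH = -1
_DIFF_GAP_OPEN = -3
_DIFF_GAP_EXTEND = -2


@njit(cache=True)
def _nw_pointers(a, b):
    """Global affine alignment of a (rows) vs b (cols); returns pointer
    matrices for traceback.  Pointer codes: 0 diagonal, 1 up (gap in b),
    2 left (gap in a)."""
    n, m = a.shape[0], b.shape[0]
    NEG = -(10**9)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)  # gap in a (left)
    F = np.empty((n + 1, m + 1), dtype=np.int64)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0
    E[0, 0] = F[0, 0] = NEG
    for j in range(1, m + 1):
        E[0, j] = _DIFF_GAP_OPEN + (j - 1) * _DIFF_GAP_EXTEND
        H[0, j] = E[0, j]
        F[0, j] = NEG
        ptr[0, j] = 2
    for i in range(1, n + 1):
        F[i, 0] = _DIFF_GAP_OPEN + (i - 1) * _DIFF_GAP_EXTEND
        H[i, 0] = F[i, 0]
        E[i, 0] = NEG
        ptr[i, 0] = 1
        for j in range(1, m + 1):
            e = max(H[i, j - 1] + _DIFF_GAP_OPEN, E[i, j - 1] + _DIFF_GAP_EXTEND)
            f = max(H[i - 1, j] + _DIFF_GAP_OPEN, F[i - 1, j] + _DIFF_GAP_EXTEND)
            s = _DIFF_MATCH if a[i - 1] == b[j - 1] else _DIFF_MISMATCH
            d = H[i - 1, j - 1] + s
            best = d
            p = 0
            if f > best:
                best = f
                p = 1
            if e > best:
                best = e
                p = 2
            H[i, j] = best
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
    return ptr


def global_diff(ref_seq: str, alt_seq: str) -> list[tuple[str, int, str, str]]:
    """Differences of ``alt_seq`` relative to ``ref_seq`` as left-aligned
    (kind, position, ref_allele, alt_allele) events, from a global alignment
    that prefers substitutions over indel pairs."""
    if ref_seq == alt_seq:
        return []
    a = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    b = np.frombuffer(alt_seq.encode(), dtype=np.uint8)
    ptr = _nw_pointers(a, b)
    i, j = len(ref_seq), len(alt_seq)
    ops: list[tuple[str, int, int]] = []  # (op, ref_pos, alt_pos) reversed
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            i -= 1
            j -= 1
            if ref_seq[i] != alt_seq[j]:
                ops.append(("X", i, j))
        elif p == 1:  # gap in alt: deletion of ref base
            i -= 1
            ops.append(("I", i, j))
        else:  # gap in ref: insertion of alt base
            j -= 1
            ops.append(("D", i, j))
    ops.reverse()
    events: list[tuple[str, int, str, str]] = []
    k = 0
    while k < len(ops):
        op, ri, ai = ops[k]
        if op == "X":
            events.append(("substitution", ri, ref_seq[ri], alt_seq[ai]))
            k += 1
        elif op == "I":
            run = 1
            while k + run < len(ops) and ops[k + run][0] == "I" \
                    and ops[k + run][1] == ri + run:
                run += 1
            pos, ref_a, _ = left_align_indel(ri, ref_seq[ri : ri + run], "", ref_seq)
            events.append(("deletion", pos, ref_a, ""))
            k += run
        else:
            run = 1
            while k + run < len(ops) and ops[k + run][0] == "D" \
                    and ops[k + run][2] == ai + run:
                run += 1
            pos, _, alt_a = left_align_indel(ri, "", alt_seq[ai : ai + run], ref_seq)
            events.append(("insertion", pos, "", alt_a))
            k += run
    return events


@dataclass
class ConsensusResult:
    """Outcome of consensus calling for one cluster."""

    cluster_id: str
    calls: list[MutationCall]
    passed: frozenset[MutationCall]
    n_reads: int
    n_aligned: int
    discarded: bool = False
    reason: str = ""


def _alt_window(ref_seq: str, event: tuple[str, int, str, str],
                a: int, b: int) -> str:
    """The reference window [a, b) with one event applied."""
    kind, pos, ref_a, alt_a = event
    win = ref_seq[a:b]
    p = pos - a
    if kind == "substitution":
        return win[:p] + alt_a + win[p + 1 :]
    if kind == "deletion":
        return win[:p] + win[p + len(ref_a) :]
    return win[:p] + alt_a + win[p:]


def call_cluster(
    reads: Sequence[NanoporeRead],
    ref: ReferenceGene,
    filt: Optional[FilterParams] = None,
    params: Optional[ScoringParams] = None,
    cluster_id: str = "cluster",
    max_reads: int = 100,
    report_min_support: float = 0.2,
    support_window: int = 10,
) -> ConsensusResult:
    """Collapse one cluster's reads into a filtered consensus call set.

    At most ``max_reads`` reads (the first in input order) contribute, since
    support fractions saturate well below that and extra reads only cost
    time.  Every aligned read spans the whole reference (infix alignment),
    so the support denominator at each position is the number of aligned
    reads.  ``calls`` contains the consensus candidates plus any raw pileup
    event whose naive carrier fraction reaches ``report_min_support`` (the
    support histogram of a mixed cluster shows up there); ``passed``
    contains only candidates surviving the filters.
    """
    filt = filt or FilterParams()
    reads = list(reads)[:max_reads]
    ref_seq = ref.nt_sequence
    L = len(ref_seq)

    alignments = []
    for read in reads:
        aln = align_semi_global(read, ref, params)
        if aln.ok:
            alignments.append((aln, read))
    n_aligned = len(alignments)
    if n_aligned == 0:
        return ConsensusResult(cluster_id, [], frozenset(), len(reads), 0,
                               discarded=True, reason="no_alignments")

    n_fwd = sum(1 for aln, _ in alignments if aln.strand == "+")
    n_rev = n_aligned - n_fwd

    # --- stage 1: column-wise majority consensus -------------------------
    sub_votes: dict[tuple[int, str], int] = {}
    del_votes: dict[int, int] = {}
    ins_votes: dict[tuple[int, str], int] = {}
    raw: dict[tuple, int] = {}
    raw_fwd: dict[tuple, int] = {}
    oriented: list[tuple[str, str, np.ndarray]] = []  # (strand, seq, ref->read map)
    for aln, read in alignments:
        seq = read.bases if aln.strand == "+" else reverse_complement(read.bases)
        oriented.append((aln.strand, seq, _ref_to_read_map(aln)))
        qpos, tpos = 0, aln.offset
        for length, op in aln.cigar:
            if op == "=":
                qpos += length
                tpos += length
            elif op == "X":
                for k in range(length):
                    sub_votes[(qpos + k, seq[tpos + k])] = \
                        sub_votes.get((qpos + k, seq[tpos + k]), 0) + 1
                qpos += length
                tpos += length
            elif op == "I":
                for k in range(length):
                    del_votes[qpos + k] = del_votes.get(qpos + k, 0) + 1
                qpos += length
            else:  # D
                pos, _, alt_a = left_align_indel(
                    qpos, "", seq[tpos : tpos + length], ref_seq)
                ins_votes[(pos, alt_a)] = ins_votes.get((pos, alt_a), 0) + 1
                tpos += length
        for event in set(_walk_alignment(aln, seq, ref_seq)):
            raw[event] = raw.get(event, 0) + 1
            if aln.strand == "+":
                raw_fwd[event] = raw_fwd.get(event, 0) + 1

    ins_at: dict[int, str] = {}
    for (pos, alt_a), count in ins_votes.items():
        if count * 2 > n_aligned:
            ins_at[pos] = alt_a
    subs_by_pos: dict[int, dict[str, int]] = {}
    for (pos, alt), c in sub_votes.items():
        subs_by_pos.setdefault(pos, {})[alt] = c
    cons_parts: list[str] = []
    for pos in range(L + 1):
        if pos in ins_at:
            cons_parts.append(ins_at[pos])
        if pos == L:
            break
        alts = subs_by_pos.get(pos)
        n_del = del_votes.get(pos, 0)
        if alts is None and n_del == 0:
            cons_parts.append(ref_seq[pos])
            continue
        # majority allele among reference base, alternates and the gap;
        # ties keep the reference
        best_base = ref_seq[pos]
        best_count = n_aligned - n_del - sum((alts or {}).values())
        for alt, c in (alts or {}).items():
            if c > best_count:
                best_base, best_count = alt, c
        if n_del > best_count:
            best_base = ""
        cons_parts.append(best_base)
    consensus_seq = "".join(cons_parts)

    # --- stage 2: diff + per-read window support -------------------------
    candidates = global_diff(ref_seq, consensus_seq)
    calls: list[MutationCall] = []
    passed: set[MutationCall] = set()
    cand_keys = set(candidates)
    for event in candidates:
        kind, pos, ref_a, alt_a = event
        a = max(0, pos - support_window)
        b = min(L, pos + len(ref_a) + support_window)
        ref_win = ref_seq[a:b]
        alt_win = _alt_window(ref_seq, event, a, b)
        n_carry = n_carry_fwd = 0
        for strand, seq, r2r in oriented:
            seg = seq[r2r[a] : r2r[b]]
            d_ref = edlib.align(seg, ref_win, mode="NW", task="distance")["editDistance"]
            d_alt = edlib.align(seg, alt_win, mode="NW", task="distance")["editDistance"]
            if d_alt < d_ref:
                n_carry += 1
                if strand == "+":
                    n_carry_fwd += 1
        support = n_carry / n_aligned
        fwd_support = n_carry_fwd / n_fwd if n_fwd else 0.0
        rev_support = (n_carry - n_carry_fwd) / n_rev if n_rev else 0.0
        call = MutationCall(position=pos, kind=kind, ref_allele=ref_a,
                            alt_allele=alt_a, support=support,
                            fwd_support=fwd_support, rev_support=rev_support)
        calls.append(call)
        if support <= filt.min_support:
            continue
        if n_fwd >= filt.min_strand_reads and n_rev >= filt.min_strand_reads:
            if (fwd_support < filt.min_strand_support
                    or rev_support < filt.min_strand_support):
                continue
        passed.add(call)

    # raw pileup events worth reporting (sub-majority alleles, e.g. the
    # support histogram of a mixed cluster)
    for event, n_carry in sorted(raw.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if event in cand_keys:
            continue
        support = n_carry / n_aligned
        if support < report_min_support:
            continue
        n_carry_fwd = raw_fwd.get(event, 0)
        calls.append(MutationCall(
            position=event[1], kind=event[0], ref_allele=event[2],
            alt_allele=event[3], support=support,
            fwd_support=n_carry_fwd / n_fwd if n_fwd else 0.0,
            rev_support=(n_carry - n_carry_fwd) / n_rev if n_rev else 0.0))

    if len(passed) > filt.max_mutations:
        return ConsensusResult(cluster_id, calls, frozenset(), len(reads),
                               n_aligned, discarded=True,
                               reason="too_many_mutations")
    return ConsensusResult(cluster_id, calls, frozenset(passed), len(reads),
                           n_aligned)


def implied_consensus(ref: ReferenceGene, calls: Iterable[MutationCall]) -> str:
    """Apply a call set to the reference, yielding the consensus sequence."""
    seq = ref.nt_sequence
    # apply right-to-left so earlier positions stay valid
    for call in sorted(calls, key=lambda c: c.position, reverse=True):
        p = call.position
        if call.kind == "substitution":
            seq = seq[:p] + call.alt_allele + seq[p + 1 :]
        elif call.kind == "deletion":
            seq = seq[:p] + seq[p + len(call.ref_allele) :]
        else:
            seq = seq[:p] + call.alt_allele + seq[p:]
    return seq


# ---------------------------------------------------------------------------
# Accuracy evaluation against simulator ground truth
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Consensus accuracy against the simulator's planted truth."""

    per_base_error: float
    fn_rate: float
    fp_rate: float
    n_true_mutations: int
    n_clusters: int
    n_excluded: int = 0

    @property
    def per_base_accuracy(self) -> float:
        return 1.0 - self.per_base_error


def majority_truth(
    clusters: Sequence[Cluster],
    reads: Sequence[NanoporeRead],
) -> dict[str, str]:
    """Map each cluster to the template providing most of its reads.

    Requires simulated reads (truth labels); clusters whose reads carry no
    truth are omitted.
    """
    truth_of = {r.read_id: r.truth.template_id for r in reads if r.truth is not None}
    out: dict[str, str] = {}
    for cl in clusters:
        labels = [truth_of[rid] for rid in cl.member_read_ids if rid in truth_of]
        if labels:
            values, counts = np.unique(labels, return_counts=True)
            out[cl.cluster_id] = str(values[np.argmax(counts)])
    return out


def evaluate_accuracy(
    results: Sequence[ConsensusResult],
    cluster_truth: Mapping[str, str],
    templates: Mapping[str, "umilink.simulate.TaggedTemplate"],
    ref: ReferenceGene,
) -> AccuracyReport:
    """Score consensus results against the planted templates.

    ``per_base_error`` is the edit distance between each cluster's implied
    consensus and its true template gene, summed over clusters and divided
    by the total true-template length.  ``fn_rate`` is the fraction of
    planted mutations (of evaluated clusters) missing from the passed calls;
    ``fp_rate`` is the number of spurious passed calls expressed as a
    fraction of the planted mutation count.
    """
    total_bases = 0
    error_bases = 0
    n_true = 0
    n_missed = 0
    n_spurious = 0
    n_clusters = 0
    n_excluded = 0
    for res in results:
        tpl_id = cluster_truth.get(res.cluster_id)
        if tpl_id is None or tpl_id not in templates:
            n_excluded += 1
            continue
        tpl = templates[tpl_id]
        n_clusters += 1
        cons = implied_consensus(ref, res.passed)
        d = edlib.align(cons, tpl.gene_sequence, mode="NW", task="distance")
        error_bases += d["editDistance"]
        total_bases += len(tpl.gene_sequence)
        true_set = set(tpl.true_mutations)
        n_true += len(true_set)
        n_missed += len(true_set - set(res.passed))
        n_spurious += len(set(res.passed) - true_set)
    return AccuracyReport(
        per_base_error=error_bases / total_bases if total_bases else 0.0,
        fn_rate=n_missed / n_true if n_true else 0.0,
        fp_rate=n_spurious / n_true if n_true else 0.0,
        n_true_mutations=n_true,
        n_clusters=n_clusters,
        n_excluded=n_excluded,
    )


def mutation_recovery(
    results: Sequence[ConsensusResult],
    cluster_truth: Mapping[str, str],
    templates: Mapping[str, "umilink.simulate.TaggedTemplate"],
) -> float:
    """Fraction of all planted mutations (across every template, recovered
    or not) that appear among the passed calls of the matching cluster."""
    matched: dict[str, set] = {}
    for res in results:
        tpl_id = cluster_truth.get(res.cluster_id)
        if tpl_id is None:
            continue
        matched.setdefault(tpl_id, set()).update(res.passed)
    total = 0
    found = 0
    for tpl_id, tpl in templates.items():
        true_set = set(tpl.true_mutations)
        total += len(true_set)
        found += len(true_set & matched.get(tpl_id, set()))
    return found / total if total else 1.0
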