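"""Lineage analysis across rounds of directed evolution.

Once every UMI cluster has been collapsed to a consensus call set, the
remaining questions are about the structure of the selected population:

* which selection round did each variant come from (barcode demultiplexing);
* which call sets are the same variant (deduplication, with per-round counts);
* how do variants relate in sequence space (similarity network over the
  symmetric-difference distance of amino-acid mutation sets, optionally laid
  out in 2-D with t-SNE for display);
* which mutation sets founded lineages (the core shared by every member of
  a network component);
* which residues became enriched between rounds (mutation-frequency ratios
  for variants persisting into the final round);
* and whether a mutation's activity effect depends on its background
  (none / magnitude / sign epistasis from relative lysate activities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from umilink.consensus import ConsensusResult
from umilink.seqio import (
    AminoAcidMutation,
    NanoporeRead,
    ReferenceGene,
    VariantRecord,
    reverse_complement,
)
from umilink.umi_cluster import Cluster, ScoringParams, umi_score


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class RoundAssignment:
    """Per-cluster round assignment from barcode alignment."""

    assignments: dict[str, tuple[int, float]] = field(default_factory=dict)

    def round_of(self, cluster_id: str) -> Optional[int]:
        entry = self.assignments.get(cluster_id)
        return entry[0] if entry else None


def demultiplex(
    clusters: Sequence[Cluster],
    reads_by_id: Mapping[str, NanoporeRead],
    barcodes: Sequence[str],
    strand_by_read: Optional[Mapping[str, str]] = None,
    params: Optional[ScoringParams] = None,
    margin_min: float = 4.0,
    window_extra: int = 15,
    max_reads_per_cluster: int = 10,
) -> RoundAssignment:
    """Assign clusters to selection rounds via their barcode region.

    For each cluster, every barcode is aligned locally against the
    barcode-proximal window of (up to ``max_reads_per_cluster``) member
    reads, oriented to construct orientation using the per-read strand from
    UMI extraction when provided (falling back to trying both ends).  A
    cluster is assigned to the barcode with the highest median score when
    its margin over the runner-up reaches ``margin_min``; otherwise it is
    left unassigned.
    """
    if not barcodes:
        raise ValueError("need at least one barcode")
    params = params or ScoringParams()
    window = max(len(b) for b in barcodes) + window_extra
    out = RoundAssignment()
    for cl in clusters:
        per_barcode: list[list[int]] = [[] for _ in barcodes]
        for rid in cl.member_read_ids[:max_reads_per_cluster]:
            read = reads_by_id[rid]
            strand = (strand_by_read or {}).get(rid)
            if strand == "+":
                windows = [read.bases[:window]]
            elif strand == "-":
                windows = [reverse_complement(read.bases)[:window]]
            else:
                windows = [read.bases[:window], reverse_complement(read.bases)[:window]]
            for bi, bc in enumerate(barcodes):
                per_barcode[bi].append(
                    max(umi_score(bc, w, params) for w in windows)
                )
        medians = [float(np.median(s)) if s else 0.0 for s in per_barcode]
        order = np.argsort(medians)[::-1]
        best, runner = int(order[0]), int(order[1]) if len(medians) > 1 else None
        margin = medians[best] - (medians[runner] if runner is not None else 0.0)
        if margin >= margin_min:
            out.assignments[cl.cluster_id] = (best, medians[best])
    return out


# ---------------------------------------------------------------------------
# Variant deduplication and distances
# ---------------------------------------------------------------------------

def dedupe_variants(
    results_by_round: Mapping[int, Sequence[ConsensusResult]],
    ref: ReferenceGene,
    umis_by_cluster: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Collapse consensus call sets to unique variants with per-round counts.

    Grouping is by the exact nucleotide mutation set; the wild type is the
    record with an empty set.  Discarded consensus results do not
    contribute.
    """
    grouped: dict[frozenset, VariantRecord] = {}
    n = 0
    for round_index in sorted(results_by_round):
        for res in results_by_round[round_index]:
            if res.discarded:
                continue
            key = frozenset(res.passed)
            if key not in grouped:
                rec = VariantRecord.from_nt_mutations(
                    variant_id=f"v{n:05d}", nt_mutations=key, ref=ref)
                grouped[key] = rec
                n += 1
            rec = grouped[key]
            rec.round_counts[round_index] = rec.round_counts.get(round_index, 0) + 1
            if umis_by_cluster and res.cluster_id in umis_by_cluster:
                rec.umis.add(umis_by_cluster[res.cluster_id])
    return list(grouped.values())


def variant_distance(a: VariantRecord, b: VariantRecord) -> int:
    """Distance in sequence space: size of the symmetric difference of the
    amino-acid mutation sets (a metric on mutation sets)."""
    return len(a.aa_mutations ^ b.aa_mutations)


# ---------------------------------------------------------------------------
# Similarity network
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNetwork:
    """Variant similarity graph with optional 2-D embedding."""

    graph: nx.Graph
    records: dict[str, VariantRecord]
    coords: Optional[dict[str, tuple[float, float]]] = None

    def components(self) -> list[list[VariantRecord]]:
        return [
            [self.records[v] for v in comp]
            for comp in nx.connected_components(self.graph)
        ]


def build_network(
    records: Sequence[VariantRecord],
    d_max: int = 2,
    embed: bool = False,
    seed: int = 7,
    perplexity: float = 30.0,
) -> SimilarityNetwork:
    """Connect variants whose pairwise distance is at most ``d_max``.

    Untranslatable variants are excluded (their amino-acid set is
    undefined).  When ``embed`` is set, a t-SNE layout of the pairwise
    distance matrix is computed with a fixed seed; the perplexity is clipped
    below the node count as required by the embedding.
    """
    usable = [r for r in records if not r.untranslatable]
    if not usable:
        raise ValueError("no translatable variants to build a network from")
    g = nx.Graph()
    for rec in usable:
        g.add_node(rec.variant_id, first_round=rec.first_round,
                   count=rec.total_count, n_mutations=len(rec.aa_mutations))
    dist = np.zeros((len(usable), len(usable)), dtype=float)
    for i, a in enumerate(usable):
        for j in range(i + 1, len(usable)):
            d = variant_distance(a, usable[j])
            dist[i, j] = dist[j, i] = d
            if d <= d_max:
                g.add_edge(a.variant_id, usable[j].variant_id, distance=d)
    coords = None
    if embed:
        from sklearn.manifold import TSNE

        perp = min(perplexity, max(1.0, (len(usable) - 1) / 3))
        xy = TSNE(n_components=2, metric="precomputed", init="random",
                  random_state=seed, perplexity=perp).fit_transform(dist)
        coords = {rec.variant_id: (float(x), float(y))
                  for rec, (x, y) in zip(usable, xy)}
    return SimilarityNetwork(graph=g,
                             records={r.variant_id: r for r in usable},
                             coords=coords)


# ---------------------------------------------------------------------------
# Founder variants
# ---------------------------------------------------------------------------

@dataclass
class FounderVariant:
    """A lineage: the mutation core shared by every member of a cluster."""

    members: list[VariantRecord]
    core: frozenset[AminoAcidMutation]
    sub_lineages: list["FounderVariant"] = field(default_factory=list)

    @property
    def core_label(self) -> str:
        return " ".join(str(m) for m in sorted(self.core, key=lambda m: m.residue)) or "WT"


def _founder_of(members: list[VariantRecord], depth: int = 0) -> FounderVariant:
    core = frozenset.intersection(*(m.aa_mutations for m in members))
    founder = FounderVariant(members=members, core=core)
    if depth >= 10:
        return founder
    # sub-lineages: members carrying the core plus at least one further
    # mutation, grouped by their next shared acquisition
    extras: dict[frozenset, list[VariantRecord]] = {}
    for m in members:
        extra = m.aa_mutations - core
        if extra:
            extras.setdefault(frozenset(extra), []).append(m)
    # group member sets whose extras intersect (shared next mutation)
    by_mutation: dict[AminoAcidMutation, list[VariantRecord]] = {}
    for extra, ms in extras.items():
        for mut in extra:
            by_mutation.setdefault(mut, []).extend(ms)
    seen: set[str] = set()
    for mut, ms in sorted(by_mutation.items(), key=lambda kv: (-len(kv[1]), str(kv[0]))):
        ms = [m for m in ms if m.variant_id not in seen]
        if not ms:
            continue
        seen.update(m.variant_id for m in ms)
        sub = _founder_of(ms, depth + 1)
        founder.sub_lineages.append(sub)
    return founder


def find_founders(
    clusters: Iterable[Sequence[VariantRecord]],
) -> list[FounderVariant]:
    """Derive founder variants from network components (or any clustering).

    The founder core of a cluster is the intersection of all members'
    amino-acid mutation sets; sub-lineages are reported by recursing on
    members that carry the core plus at least one further shared mutation.
    """
    founders = []
    for members in clusters:
        members = list(members)
        if not members:
            raise ValueError("founder clusters must be non-empty")
        founders.append(_founder_of(members))
    return founders


# ---------------------------------------------------------------------------
# Positional enrichment (hot-spots)
# ---------------------------------------------------------------------------

def positional_enrichment(
    records: Sequence[VariantRecord],
    round_from: int = 1,
    round_to: int = 2,
    persist_round: int = 3,
    eps: Optional[float] = None,
) -> dict[int, float]:
    """Per-residue mutation-frequency enrichment between two rounds.

    Only variants still observed in ``persist_round`` qualify.  For each
    round k the frequency of residue r is the count-weighted fraction of
    qualifying variants mutated at r; the enrichment factor is
    ``(f_to + ε) / (f_from + ε)``.  The pseudocount ε keeps factors finite
    when a residue is absent from one round; by default it adapts to the
    dataset as ``1 / (total qualifying count over both rounds)``.  Since the
    frequencies are fractions, factors computed at a fixed ε are invariant
    under a uniform rescaling of all counts.
    """
    qualifying = [r for r in records
                  if r.round_counts.get(persist_round, 0) > 0 and not r.untranslatable]
    totals = {}
    for k in (round_from, round_to):
        totals[k] = sum(r.round_counts.get(k, 0) for r in qualifying)
        if totals[k] == 0:
            raise ValueError(f"no qualifying variants observed in round {k}")
    if eps is None:
        eps = 1.0 / (totals[round_from] + totals[round_to])

    def freq(residue: int, k: int) -> float:
        w = sum(r.round_counts.get(k, 0) for r in qualifying
                if any(m.residue == residue for m in r.aa_mutations))
        return w / totals[k]

    residues = sorted({m.residue for r in qualifying for m in r.aa_mutations})
    return {
        res: (freq(res, round_to) + eps) / (freq(res, round_from) + eps)
        for res in residues
    }


# ---------------------------------------------------------------------------
# Epistasis classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityRecord:
    """Relative lysate activity of one mutation set (parent = 1.0).

    ``ci95`` is the half-width of the 95% confidence interval of the
    activity, on the same relative scale.
    """

    mutations: frozenset[AminoAcidMutation]
    relative_activity: float
    ci95: float = 0.0

    def __post_init__(self) -> None:
        if self.relative_activity < 0:
            raise ValueError("relative activity must be >= 0")
        if self.ci95 < 0:
            raise ValueError("ci95 must be >= 0")


@dataclass
class EpistasisCall:
    """Classification of one mutation's context dependence."""

    kind: str  # none | magnitude | sign | undefined
    effect_alone: float
    effect_in_background: float
    ci_alone: float = 0.0
    ci_in_background: float = 0.0


def _ratio_with_ci(num: ActivityRecord, den: ActivityRecord) -> tuple[float, float]:
    """Ratio of two activities with Gaussian propagation of the 95% CIs."""
    if den.relative_activity == 0:
        raise ZeroDivisionError
    r = num.relative_activity / den.relative_activity
    rel = 0.0
    if num.relative_activity > 0:
        rel += (num.ci95 / num.relative_activity) ** 2
    rel += (den.ci95 / den.relative_activity) ** 2
    return r, r * rel**0.5


def classify_epistasis(
    activities: Mapping[frozenset, ActivityRecord],
    mutation: AminoAcidMutation,
    background: frozenset[AminoAcidMutation],
    magnitude_ratio: float = 1.5,
) -> EpistasisCall:
    """Classify the interaction of ``mutation`` with ``background``.

    Requires activities for the parent (empty set), the single mutation,
    the background, and background plus mutation.  With ``e_alone`` the
    mutation's activity effect on the parent and ``e_bg`` its effect inside
    the background:

    * sign epistasis: the effects lie on opposite sides of 1 and both 95%
      CIs exclude 1;
    * magnitude epistasis: same side of 1 but the effects differ by more
      than ``magnitude_ratio``-fold;
    * none: otherwise.

    For a mutation pair (``background`` of size one) sign epistasis is a
    property of the pair — the interaction flips the sign of at least one
    member's effect — so the swapped orientation is checked as well and the
    classification is symmetric under relabelling.
    """
    needed = [frozenset(), frozenset({mutation}), frozenset(background),
              frozenset(background) | {mutation}]
    for key in needed:
        if key not in activities:
            raise KeyError(f"missing activity record for {set(key) or 'parent'}")
    parent, alone, bg, combined = (activities[k] for k in needed)
    try:
        e_alone, ci_alone = _ratio_with_ci(alone, parent)
        e_bg, ci_bg = _ratio_with_ci(combined, bg)
    except ZeroDivisionError:
        return EpistasisCall(kind="undefined", effect_alone=float("nan"),
                             effect_in_background=float("nan"))

    call = EpistasisCall(kind="none", effect_alone=e_alone,
                         effect_in_background=e_bg,
                         ci_alone=ci_alone, ci_in_background=ci_bg)

    def is_sign(e1, c1, e2, c2):
        return (e1 - 1.0) * (e2 - 1.0) < 0 and abs(e1 - 1.0) > c1 \
            and abs(e2 - 1.0) > c2

    sign = is_sign(e_alone, ci_alone, e_bg, ci_bg)
    if not sign and len(background) == 1:
        # pair case: also test whether the partner's effect flips sign
        partner = next(iter(background))
        try:
            e2_alone, c2_alone = _ratio_with_ci(
                activities[frozenset({partner})], parent)
            e2_bg, c2_bg = _ratio_with_ci(combined, alone)
        except ZeroDivisionError:
            e2_alone = e2_bg = None
        if e2_alone is not None:
            sign = is_sign(e2_alone, c2_alone, e2_bg, c2_bg)
    if sign:
        call.kind = "sign"
        return call
    if (e_alone - 1.0) * (e_bg - 1.0) >= 0 and e_alone > 0 and e_bg > 0:
        fold = max(e_alone / e_bg, e_bg / e_alone)
        if fold > magnitude_ratio:
            call.kind = "magnitude"
    return call
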