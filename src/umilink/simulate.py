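"""Ground-truthed simulation of UMI-tagged amplicon libraries and long reads.

The simulator emulates the experimental workflow end to end:

1. an error-prone-PCR library of gene variants — mutation counts are
   Poisson-distributed (mean 3.5 per gene by default), positions uniform
   without replacement, substitutions uniform over the three alternatives;
2. UMI tagging — every template receives a unique random UMI (50 bp by
   default) plus a round-specific barcode, in the fixed construct layout
   ``[barcode][gene][probe][UMI]`` with a 20-nt constant probe adjacent to
   the UMI;
3. nanopore-like reads — per-base i.i.d. substitution/insertion/deletion
   errors with a configurable split, covering the 85–95% raw-accuracy regime;
   strand drawn uniformly, with reverse-strand reads emitted as reverse
   complements.

Every read carries its ground truth (template, UMI, planted mutations), so
clustering, consensus calling and demultiplexing can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from umilink.seqio import (
    MutationCall,
    NanoporeRead,
    ReadTruth,
    ReferenceGene,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

#: Constant anchor between gene and UMI, used to locate the UMI in a read.
DEFAULT_PROBE = "CAGTGCTAGGTCACTGACGT"

#: Sense codons only (no stops), used when synthesising reference genes.
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASE_STR, repeat=3)
    if "".join(c) not in _STOP_CODONS
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. read error process.

    Rates are per-base probabilities; total read accuracy is
    ``1 - (sub_rate + ins_rate + del_rate)``.  The combined rate is capped at
    0.2 (80% accuracy), below the worst raw nanopore accuracy this workflow
    is designed for.
    """

    sub_rate: float = 0.06
    ins_rate: float = 0.02
    del_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if r < 0:
                raise ValueError("error rates must be non-negative")
        if self.total_rate > 0.2:
            raise ValueError("combined error rate above 0.2 is unsupported")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @classmethod
    def from_total(cls, total: float, seed: int = 0,
                   split: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> "ErrorModel":
        """Split an aggregate per-base error rate into sub/ins/del components."""
        s = sum(split)
        return cls(sub_rate=total * split[0] / s, ins_rate=total * split[1] / s,
                   del_rate=total * split[2] / s, seed=seed)


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of one UMI-tagged error-prone-PCR library."""

    n_templates: int
    mean_mutations: float = 3.5
    umi_length: int = 50
    barcode: str = ""
    probe: str = DEFAULT_PROBE
    round_index: int = 0
    # optional transition/transversion bias: base -> {alt: weight}; uniform when None
    substitution_bias: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.mean_mutations < 0:
            raise ValueError("mean_mutations must be >= 0")


@dataclass(frozen=True)
class TaggedTemplate:
    """One UMI-tagged library molecule with its planted ground truth."""

    template_id: str
    umi: str
    barcode: str
    nt_sequence: str  # full construct [barcode][gene][probe][umi]
    gene_sequence: str
    true_mutations: frozenset[MutationCall]
    round_index: int = 0


def make_reference(
    n_codons: int = 416,
    seed: int = 0,
    name: str = "parent",
    forced_codons: Optional[Mapping[int, str]] = None,
) -> ReferenceGene:
    """Synthesise a random reference gene with a clean open reading frame.

    ``forced_codons`` pins specific codons (1-based residue numbers), which
    tests use to realise particular amino-acid mutation names.
    """
    rng = np.random.default_rng(seed)
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons)]
    for residue, codon in (forced_codons or {}).items():
        if codon in _STOP_CODONS:
            raise ValueError("cannot force a stop codon into the reference")
        codons[residue - 1] = codon
    seq = "".join(codons)
    return ReferenceGene(name=name, nt_sequence=seq, cds_offset=0, cds_length=len(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate_gene(
    gene: str,
    n_mut: int,
    rng: np.random.Generator,
    bias: Optional[Mapping[str, Mapping[str, float]]],
) -> tuple[str, frozenset[MutationCall]]:
    positions = rng.choice(len(gene), size=n_mut, replace=False)
    seq = list(gene)
    muts = []
    for pos in sorted(int(p) for p in positions):
        ref_base = gene[pos]
        alts = [b for b in _BASE_STR if b != ref_base]
        if bias is not None:
            w = np.array([bias[ref_base].get(a, 1.0) for a in alts], dtype=float)
            alt = alts[rng.choice(3, p=w / w.sum())]
        else:
            alt = alts[rng.integers(0, 3)]
        seq[pos] = alt
        muts.append(MutationCall(position=pos, kind="substitution",
                                 ref_allele=ref_base, alt_allele=alt))
    return "".join(seq), frozenset(muts)


def generate_library(
    ref: ReferenceGene,
    cfg: LibraryConfig,
    seed: int = 0,
) -> list[TaggedTemplate]:
    """Generate a UMI-tagged error-prone-PCR library.

    Per template the mutation count is Poisson(``mean_mutations``), positions
    are uniform without replacement over the gene, and each substitution is
    uniform over the three alternative bases (or biased when a weight table
    is configured).  UMIs are uniform random and regenerated on collision so
    that all UMIs in one library are pairwise distinct.  Deterministic for a
    given seed.
    """
    gene = ref.nt_sequence
    if cfg.mean_mutations > len(gene):
        raise ValueError("mean_mutations exceeds gene length")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(cfg.mean_mutations, size=cfg.n_templates)
    counts = np.minimum(counts, len(gene))
    seen_umis: set[str] = set()
    templates: list[TaggedTemplate] = []
    for i in range(cfg.n_templates):
        mut_gene, muts = _mutate_gene(gene, int(counts[i]), rng, cfg.substitution_bias)
        umi = _random_seq(rng, cfg.umi_length)
        while umi in seen_umis:
            umi = _random_seq(rng, cfg.umi_length)
        seen_umis.add(umi)
        construct = cfg.barcode + mut_gene + cfg.probe + umi
        templates.append(TaggedTemplate(
            template_id=f"r{cfg.round_index}_t{i:06d}",
            umi=umi,
            barcode=cfg.barcode,
            nt_sequence=construct,
            gene_sequence=mut_gene,
            true_mutations=muts,
            round_index=cfg.round_index,
        ))
    return templates


def apply_read_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitution/deletion errors and single-base
    insertions (inserted after a base) to a sequence."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = codes.size
    draw = rng.random(n)
    del_mask = draw < model.del_rate
    sub_mask = (draw >= model.del_rate) & (draw < model.del_rate + model.sub_rate)
    if sub_mask.any():
        # substitute with one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, codes[sub_mask])
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        codes[sub_mask] = _BASES[(idx + shift) % 4]
    ins_mask = rng.random(n) < model.ins_rate
    keep = ~del_mask
    out_counts = keep.astype(np.int64) + ins_mask.astype(np.int64)
    offsets = np.concatenate(([0], np.cumsum(out_counts)[:-1]))
    out = np.empty(int(out_counts.sum()), dtype=np.uint8)
    out[offsets[keep]] = codes[keep]
    if ins_mask.any():
        ins_codes = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
        out[(offsets + keep)[ins_mask]] = ins_codes
    return out.tobytes().decode()


def simulate_reads(
    templates: Sequence[TaggedTemplate],
    coverage: int,
    error_model: ErrorModel,
) -> list[NanoporeRead]:
    """Emit exactly ``coverage`` erroneous reads per template.

    Strand is drawn uniformly; reverse-strand reads are emitted as the
    reverse complement of the erroneous construct.  Ground truth is attached
    to every read.  Deterministic for a given ``error_model.seed``.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(error_model.seed)
    reads: list[NanoporeRead] = []
    for tpl in templates:
        truth = ReadTruth(template_id=tpl.template_id, true_umi=tpl.umi,
                          true_mutations=tpl.true_mutations,
                          round_index=tpl.round_index)
        for j in range(coverage):
            bases = apply_read_errors(tpl.nt_sequence, error_model, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                bases = reverse_complement(bases)
            reads.append(NanoporeRead(
                read_id=f"{tpl.template_id}_read{j:03d}",
                bases=bases, strand=strand, truth=truth,
            ))
    return reads


def random_barcodes(n: int, length: int = 24, seed: int = 0,
                    min_pairwise_diff: int = 10) -> list[str]:
    """Draw round barcodes with a guaranteed minimum pairwise Hamming
    distance, mimicking commercial multiplexing barcode sets."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_pairwise_diff for bc in out):
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# UMI-length clustering-efficiency simulation
# ---------------------------------------------------------------------------

def simulate_clustering_efficiency(
    umi_lengths: Sequence[int],
    error_rates: Sequence[float],
    library_sizes: Sequence[int],
    reads_per_umi: int = 10,
    seed: int = 0,
) -> "pandas.DataFrame":
    """Clustering quality across UMI lengths, read error rates and library sizes.

    For each grid point: draw ``library_size`` distinct random UMIs, emit
    ``reads_per_umi`` erroneous copies of each (aggregate error split
    sub:ins:del = 0.6:0.2:0.2), cluster the copies greedily and score the
    result against the known template of each copy.

    Returns a table with columns ``umi_length, error_rate, library_size,
    recollection, homogeneity``, where recollection is the fraction of true
    templates recovered as the majority label of some cluster and homogeneity
    is the mean within-cluster fraction of copies sharing the majority label.

    The clustering threshold at each grid point is set from the ground truth
    as the midpoint between the mean same-template and mean cross-template
    alignment scores (truth is available here by construction; on real data
    use :func:`umilink.umi_cluster.estimate_threshold`).
    """
    import pandas as pd

    from umilink.umi_cluster import ScoringParams, UMIExtraction, cluster_greedy, umi_score

    if not (umi_lengths and error_rates and library_sizes):
        raise ValueError("all parameter lists must be non-empty")
    rows = []
    base_rng = np.random.default_rng(seed)
    for L in umi_lengths:
        for err in error_rates:
            for size in library_sizes:
                sub_seed = int(base_rng.integers(0, 2**31 - 1))
                rng = np.random.default_rng(sub_seed)
                umis: list[str] = []
                seen: set[str] = set()
                while len(umis) < size:
                    u = _random_seq(rng, L)
                    if u not in seen:
                        seen.add(u)
                        umis.append(u)
                model = ErrorModel.from_total(err, seed=sub_seed)
                copies: list[UMIExtraction] = []
                labels: list[int] = []
                for t, u in enumerate(umis):
                    for j in range(reads_per_umi):
                        noisy = apply_read_errors(u, model, rng) if err > 0 else u
                        copies.append(UMIExtraction(
                            read_id=f"t{t}_c{j}", umi=noisy, anchor_score=0.0, ok=True))
                        labels.append(t)
                params = ScoringParams()
                if err > 0:
                    # truth-aware threshold: midpoint of self vs cross score means
                    n_pairs = min(200, size)
                    self_scores = []
                    cross_scores = []
                    for _ in range(n_pairs):
                        t = int(rng.integers(0, size))
                        a = apply_read_errors(umis[t], model, rng)
                        b = apply_read_errors(umis[t], model, rng)
                        self_scores.append(umi_score(a, b, params))
                        t2 = int(rng.integers(0, size))
                        u2 = int(rng.integers(0, size))
                        if t2 == u2:
                            u2 = (u2 + 1) % size
                        cross_scores.append(umi_score(umis[t2], umis[u2], params))
                    thr = int(round((np.mean(self_scores) + np.mean(cross_scores)) / 2))
                else:
                    thr = L * params.match
                params = ScoringParams(threshold=thr)
                # drop empty copies (possible for very short UMIs at high error)
                kept = [(c, l) for c, l in zip(copies, labels) if c.umi]
                clusters = cluster_greedy([c for c, _ in kept], params)
                label_of = {c.read_id: l for c, l in kept}
                recovered: set[int] = set()
                homogeneities = []
                for cl in clusters:
                    member_labels = [label_of[rid] for rid in cl.member_read_ids]
                    values, cnts = np.unique(member_labels, return_counts=True)
                    maj = int(values[np.argmax(cnts)])
                    recovered.add(maj)
                    homogeneities.append(cnts.max() / len(member_labels))
                rows.append({
                    "umi_length": L, "error_rate": err, "library_size": size,
                    "recollection": len(recovered) / size,
                    "homogeneity": float(np.mean(homogeneities)) if homogeneities else 0.0,
                })
    return pd.DataFrame(rows)
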