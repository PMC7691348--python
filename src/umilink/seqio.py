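"""Domain types, sequence I/O and mutation-notation conventions.

Conventions used throughout the package:

* nucleotide coordinates are 0-based half-open on the reference;
* protein residues are numbered 1-based, rendered in the field's usual
  ``A64E`` style (reference amino acid, residue, alternate amino acid);
* insertions and deletions are left-aligned (shifted to the smallest
  equivalent reference position) so that equivalent calls deduplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SIMULATED_ALPHABET = frozenset("ACGT")
PARSED_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FrameshiftError(ValueError):
    """An indel inside the CDS makes the variant untranslatable."""


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth annotation attached to simulated reads only."""

    template_id: str
    true_umi: str
    true_mutations: frozenset["MutationCall"]
    round_index: int = 0


@dataclass
class NanoporeRead:
    """A single long read, either parsed from FASTQ or simulated.

    ``truth`` is populated only by the simulator and carries the identity of
    the template molecule the read descends from.
    """

    read_id: str
    bases: str
    strand: str = "+"
    truth: Optional[ReadTruth] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        alphabet = SIMULATED_ALPHABET if self.truth is not None else PARSED_ALPHABET
        extra = set(self.bases) - alphabet
        if extra:
            raise ValueError(
                f"read {self.read_id!r} contains invalid bases {sorted(extra)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReferenceGene:
    """Parental gene used as alignment reference.

    The CDS (``cds_offset``, ``cds_length``) defines the reading frame for
    rendering amino-acid mutation names.
    """

    name: str
    nt_sequence: str
    cds_offset: int = 0
    cds_length: int = -1

    def __post_init__(self) -> None:
        if self.cds_length < 0:
            # default: largest in-frame stretch from cds_offset
            object.__setattr__(
                self,
                "cds_length",
                (len(self.nt_sequence) - self.cds_offset) // 3 * 3,
            )
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        if self.cds_offset + self.cds_length > len(self.nt_sequence):
            raise ValueError("CDS extends past end of reference sequence")
        prot = self.protein_sequence
        if "*" in prot[:-1]:
            raise ValueError(f"reference CDS of {self.name!r} has internal stop")

    @property
    def cds(self) -> str:
        return self.nt_sequence[self.cds_offset : self.cds_offset + self.cds_length]

    @property
    def protein_sequence(self) -> str:
        return str(Seq(self.cds).translate())

    def __len__(self) -> int:
        return len(self.nt_sequence)


@dataclass(frozen=True)
class MutationCall:
    """One reference-relative difference with its read support.

    ``position`` is 0-based on the reference nucleotide sequence.  For
    substitutions both alleles have length 1; insertions have an empty
    ``ref_allele`` (bases inserted before ``position``); deletions have an
    empty ``alt_allele``.  Support fractions are informational and excluded
    from equality/hashing so that identical calls from different clusters
    compare equal.
    """

    position: int
    kind: str
    ref_allele: str
    alt_allele: str
    support: float = field(default=1.0, compare=False)
    fwd_support: float = field(default=1.0, compare=False)
    rev_support: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("substitution alleles must have length 1")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution ref and alt must differ")
        elif self.kind == "insertion":
            if self.ref_allele != "" or not self.alt_allele:
                raise ValueError("insertion must have empty ref and non-empty alt")
        elif self.kind == "deletion":
            if self.alt_allele != "" or not self.ref_allele:
                raise ValueError("deletion must have empty alt and non-empty ref")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 0:
            raise ValueError("position must be non-negative")
        for frac in (self.support, self.fwd_support, self.rev_support):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("support fractions must lie in [0, 1]")

    def __str__(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref_allele}{self.position}{self.alt_allele}"
        if self.kind == "insertion":
            return f"{self.position}ins{self.alt_allele}"
        return f"{self.position}del{self.ref_allele}"


def left_align_indel(
    position: int, ref_allele: str, alt_allele: str, reference: str
) -> tuple[int, str, str]:
    """Shift an indel to its smallest equivalent reference position.

    Uses the standard normalisation: while the base preceding the event
    equals the last base of the inserted/deleted sequence, the event can be
    rotated one position to the left without changing the resulting sequence.
    Idempotent; substitutions are returned unchanged.
    """
    if ref_allele and alt_allele:  # substitution
        return position, ref_allele, alt_allele
    allele = ref_allele or alt_allele
    pos = position
    while pos > 0 and reference[pos - 1] == allele[-1]:
        allele = reference[pos - 1] + allele[:-1]
        pos -= 1
    if ref_allele:
        return pos, allele, ""
    return pos, "", allele


@dataclass(frozen=True)
class AminoAcidMutation:
    """Protein-level mutation in one-letter code, e.g. ``A64E``."""

    ref_aa: str
    residue: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError("residue numbers are 1-based")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"

    @classmethod
    def parse(cls, text: str) -> "AminoAcidMutation":
        return cls(ref_aa=text[0], residue=int(text[1:-1]), alt_aa=text[-1])


def translate_mutations(
    nt_mutations: Iterable[MutationCall], ref: ReferenceGene
) -> frozenset[AminoAcidMutation]:
    """Render nucleotide mutations as amino-acid changes.

    Substitutions falling in the same codon are applied jointly before
    re-translation; synonymous changes produce no output.  Substitutions
    outside the CDS are ignored.  Indels inside the CDS raise
    :class:`FrameshiftError` — callers mark such variants untranslatable
    rather than silently dropping them.
    """
    cds_start = ref.cds_offset
    cds_end = ref.cds_offset + ref.cds_length
    by_codon: dict[int, list[MutationCall]] = {}
    for mut in nt_mutations:
        if mut.kind != "substitution":
            if cds_start <= mut.position < cds_end:
                raise FrameshiftError(
                    f"frameshift: {mut.kind} at position {mut.position} inside CDS"
                )
            continue
        if not cds_start <= mut.position < cds_end:
            continue
        codon_idx = (mut.position - cds_start) // 3
        by_codon.setdefault(codon_idx, []).append(mut)

    out: set[AminoAcidMutation] = set()
    for codon_idx, muts in by_codon.items():
        codon_off = cds_start + 3 * codon_idx
        codon = list(ref.nt_sequence[codon_off : codon_off + 3])
        ref_aa = str(Seq("".join(codon)).translate())
        for mut in muts:
            within = mut.position - codon_off
            if codon[within] != mut.ref_allele:
                raise ValueError(
                    f"ref allele mismatch at {mut.position}: reference has "
                    f"{codon[within]!r}, call claims {mut.ref_allele!r}"
                )
            codon[within] = mut.alt_allele
        alt_aa = str(Seq("".join(codon)).translate())
        if alt_aa != ref_aa:
            out.add(AminoAcidMutation(ref_aa=ref_aa, residue=codon_idx + 1, alt_aa=alt_aa))
    return frozenset(out)


@dataclass
class VariantRecord:
    """A deduplicated variant: one unique set of nucleotide mutations.

    ``aa_mutations`` is the deterministic translation of ``nt_mutations``;
    variants with a frameshifting indel inside the CDS are kept but flagged
    ``untranslatable`` and carry an empty amino-acid set.
    """

    variant_id: str
    nt_mutations: frozenset[MutationCall]
    aa_mutations: frozenset[AminoAcidMutation]
    round_counts: dict[int, int] = field(default_factory=dict)
    umis: set[str] = field(default_factory=set)
    untranslatable: bool = False

    @classmethod
    def from_nt_mutations(
        cls,
        variant_id: str,
        nt_mutations: Iterable[MutationCall],
        ref: ReferenceGene,
        round_counts: Optional[Mapping[int, int]] = None,
        umis: Optional[Iterable[str]] = None,
    ) -> "VariantRecord":
        nt = frozenset(nt_mutations)
        try:
            aa = translate_mutations(nt, ref)
            untranslatable = False
        except FrameshiftError:
            aa = frozenset()
            untranslatable = True
        return cls(
            variant_id=variant_id,
            nt_mutations=nt,
            aa_mutations=aa,
            round_counts=dict(round_counts or {}),
            umis=set(umis or ()),
            untranslatable=untranslatable,
        )

    @property
    def total_count(self) -> int:
        return sum(self.round_counts.values())

    @property
    def first_round(self) -> Optional[int]:
        present = [r for r, c in self.round_counts.items() if c > 0]
        return min(present) if present else None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[NanoporeRead]:
    """Parse a 4-line FASTQ file into reads (quality strings are discarded).

    The consensus method is base-space majority voting on support fractions,
    so per-base qualities are not used downstream.
    """
    path = Path(path)
    reads: list[NanoporeRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(NanoporeRead(read_id=rec.id, bases=str(rec.seq).upper()))
    except ValueError as exc:
        lineno = len(reads) * 4 + 1
        raise ValueError(f"malformed FASTQ record near line {lineno}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[NanoporeRead], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.bases), id=r.read_id, description="",
                  letter_annotations={"phred_quality": [30] * len(r.bases)})
        for r in reads
    ]
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(entries: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reference(path: str | Path, name: Optional[str] = None) -> ReferenceGene:
    """Load the parental reference gene from a (single-record) FASTA file."""
    entries = read_fasta(path)
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    if name is None:
        name = next(iter(entries))
    return ReferenceGene(name=name, nt_sequence=entries[name])
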