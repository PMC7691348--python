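"""Back-of-envelope run planning for UMI-linked consensus sequencing.

Small helpers answering the questions asked before a run: how many raw
reads (and how much data) a library needs at a given consensus coverage,
how many consensus sequences a flow cell can yield, and how many occupied
droplets a screen interrogates.
"""

from __future__ import annotations


def reads_for_coverage(n_fragments: int, coverage: int) -> int:
    """Raw reads required to sequence ``n_fragments`` UMI-tagged molecules
    at ``coverage``-fold oversampling."""
    if n_fragments < 0 or coverage < 0:
        raise ValueError("arguments must be non-negative")
    return n_fragments * coverage


def data_volume_gb(n_reads: int, read_length_bp: int) -> float:
    """Sequencing data volume in gigabases for ``n_reads`` reads of the
    given length."""
    return n_reads * read_length_bp / 1e9


def consensus_yield(flowcell_gb: float, gene_length_bp: int, coverage: int) -> float:
    """Number of consensus sequences obtainable from a flow cell of
    ``flowcell_gb`` gigabases at the given gene length and coverage."""
    if gene_length_bp <= 0 or coverage <= 0:
        raise ValueError("gene length and coverage must be positive")
    return flowcell_gb * 1e9 / (gene_length_bp * coverage)


def occupied_droplets(n_droplets: int, occupancy: float) -> float:
    """Expected number of cell-occupied droplets at the given occupancy
    fraction."""
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must be a fraction in [0, 1]")
    return n_droplets * occupancy
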