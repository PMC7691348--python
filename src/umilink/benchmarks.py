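"""Ground-truthed benchmark runs of the full pipeline.

These drive the whole workflow — library generation, read simulation, UMI
extraction, threshold estimation, clustering, consensus calling — on a
simulated library and score the result against the planted truth.  They are
used by the acceptance script and the test suite; problem sizes follow the
workflow's standard operating point (1250-bp gene, mean 3.5 mutations,
aggregate 10% read error split 6/2/2 over substitutions, insertions and
deletions).
"""

from __future__ import annotations

import numpy as np

from umilink.consensus import (
    FilterParams,
    call_cluster,
    evaluate_accuracy,
    majority_truth,
    mutation_recovery,
)
from umilink.seqio import ReferenceGene
from umilink.simulate import (
    ErrorModel,
    LibraryConfig,
    generate_library,
    make_reference,
    simulate_reads,
)
from umilink.umi_cluster import ScoringParams, cluster_greedy, estimate_threshold, extract_umi


def reference_1250(seed: int) -> ReferenceGene:
    """A 1250-bp reference: 416 sense codons plus a 2-nt non-coding tail."""
    core = make_reference(n_codons=416, seed=seed)
    return ReferenceGene(name=core.name, nt_sequence=core.nt_sequence + "GT",
                         cds_offset=0, cds_length=1248)


def consensus_accuracy_benchmark(
    n_templates: int,
    coverage: int,
    seed: int,
    total_error: float = 0.10,
    min_reads: int = 15,
) -> dict:
    """Run the full pipeline on a fresh simulated library and score it.

    Returns per-base consensus accuracy/error (percent), the fraction of
    planted mutations recovered by the passed calls (percent, with every
    planted mutation of every template in the denominator), and FN/FP rates
    over the evaluated clusters.
    """
    rng = np.random.default_rng(seed)
    ref = reference_1250(int(rng.integers(0, 2**31 - 1)))
    cfg = LibraryConfig(n_templates=n_templates)
    templates = generate_library(ref, cfg, seed=int(rng.integers(0, 2**31 - 1)))
    model = ErrorModel.from_total(total_error,
                                  seed=int(rng.integers(0, 2**31 - 1)))
    reads = simulate_reads(templates, coverage, model)

    extractions = [e for e in
                   (extract_umi(r, cfg.probe, cfg.umi_length) for r in reads)
                   if e.ok]
    est = estimate_threshold([e.umi for e in extractions],
                             thresholds=range(5, cfg.umi_length + 1),
                             seed=int(rng.integers(0, 2**31 - 1)))
    clusters = cluster_greedy(extractions, ScoringParams(threshold=est.threshold))

    reads_by_id = {r.read_id: r for r in reads}
    cluster_truth = majority_truth(clusters, reads)
    results = [
        call_cluster([reads_by_id[rid] for rid in cl.member_read_ids],
                     ref, FilterParams(), cluster_id=cl.cluster_id)
        for cl in clusters if len(cl) >= min_reads
    ]
    template_map = {t.template_id: t for t in templates}
    report = evaluate_accuracy(results, cluster_truth, template_map, ref)
    recovery = mutation_recovery(results, cluster_truth, template_map)
    return {
        "n_templates": n_templates,
        "coverage": coverage,
        "threshold": est.threshold,
        "n_clusters": len(clusters),
        "n_evaluated": report.n_clusters,
        "per_base_accuracy_pct": 100.0 * report.per_base_accuracy,
        "per_base_error_pct": 100.0 * report.per_base_error,
        "recovery_pct": 100.0 * recovery,
        "fn_rate_pct": 100.0 * report.fn_rate,
        "fp_rate_pct": 100.0 * report.fp_rate,
        "n_true_mutations": report.n_true_mutations,
    }


def library_calibration(n_templates: int, seed: int,
                        mean_mutations: float = 3.5) -> dict:
    """Sample mean mutation load of a freshly generated library."""
    rng = np.random.default_rng(seed)
    ref = reference_1250(int(rng.integers(0, 2**31 - 1)))
    lib = generate_library(
        ref, LibraryConfig(n_templates=n_templates,
                           mean_mutations=mean_mutations),
        seed=int(rng.integers(0, 2**31 - 1)))
    counts = np.array([len(t.true_mutations) for t in lib])
    return {
        "n_templates": n_templates,
        "mean_mutations": float(counts.mean()),
        "standard_error": float(np.sqrt(mean_mutations / n_templates)),
    }
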