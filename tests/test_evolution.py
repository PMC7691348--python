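"""Demultiplexing, variant deduplication, similarity networks, founders,
enrichment and epistasis classification."""

from __future__ import annotations

import numpy as np
import pytest

from umilink.consensus import ConsensusResult, call_cluster, majority_truth
from umilink.evolution import (
    ActivityRecord,
    classify_epistasis,
    build_network,
    dedupe_variants,
    demultiplex,
    find_founders,
    positional_enrichment,
    variant_distance,
)
from umilink.seqio import AminoAcidMutation, MutationCall, VariantRecord
from umilink.simulate import (
    ErrorModel,
    LibraryConfig,
    generate_library,
    random_barcodes,
    simulate_reads,
)
from umilink.umi_cluster import ScoringParams, cluster_greedy, extract_umi


def aa(text):
    return AminoAcidMutation.parse(text)


def aaset(*texts):
    return frozenset(aa(t) for t in texts)


def record(variant_id, *mut_names, rounds=None):
    return VariantRecord(variant_id=variant_id,
                         nt_mutations=frozenset(),
                         aa_mutations=aaset(*mut_names),
                         round_counts=dict(rounds or {}))


class TestDemultiplex:
    def _simulate_rounds(self, ref, n_rounds=3, n_templates=12, coverage=15,
                         error=ErrorModel(0.06, 0.02, 0.02, seed=50)):
        barcodes = random_barcodes(n_rounds, seed=51)
        reads = []
        for rnd, bc in enumerate(barcodes):
            cfg = LibraryConfig(n_templates=n_templates, barcode=bc,
                                round_index=rnd)
            lib = generate_library(ref, cfg, seed=52 + rnd)
            model = ErrorModel(error.sub_rate, error.ins_rate, error.del_rate,
                               seed=53 + rnd)
            reads.extend(simulate_reads(lib, coverage, model))
        return barcodes, reads

    def test_three_round_assignment_accuracy(self, ref):
        barcodes, reads = self._simulate_rounds(ref)
        cfg_probe = LibraryConfig(n_templates=1).probe
        exts = [e for e in (extract_umi(r, cfg_probe, 50) for r in reads) if e.ok]
        clusters = [cl for cl in cluster_greedy(exts, ScoringParams(threshold=20))
                    if len(cl) >= 8]
        reads_by = {r.read_id: r for r in reads}
        strand = {e.read_id: e.strand for e in exts}
        assignment = demultiplex(clusters, reads_by, barcodes,
                                 strand_by_read=strand)
        correct = total = 0
        for cl in clusters:
            rnd = assignment.round_of(cl.cluster_id)
            if rnd is None:
                continue
            total += 1
            true_rounds = [reads_by[rid].truth.round_index
                           for rid in cl.member_read_ids]
            correct += rnd == int(np.bincount(true_rounds).argmax())
        assert total >= 0.9 * len(clusters)
        assert correct / total >= 0.99

    def test_single_barcode_error_free_all_assigned(self, ref):
        barcodes, reads = self._simulate_rounds(
            ref, n_rounds=1, coverage=5, error=ErrorModel(0, 0, 0, seed=0))
        # use perfect clustering from truth to isolate the demultiplexer
        from collections import defaultdict
        from umilink.umi_cluster import Cluster
        groups = defaultdict(list)
        for r in reads:
            groups[r.truth.template_id].append(r.read_id)
        clusters = [Cluster(cluster_id=k, seed_umi="", member_read_ids=v)
                    for k, v in groups.items()]
        reads_by = {r.read_id: r for r in reads}
        assignment = demultiplex(clusters, reads_by, barcodes)
        assert all(assignment.round_of(cl.cluster_id) == 0 for cl in clusters)

    def test_randomised_barcode_region_unassigned(self, ref):
        rng = np.random.default_rng(55)
        barcodes = random_barcodes(2, seed=56)
        from umilink.umi_cluster import Cluster
        from umilink.seqio import NanoporeRead

        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        reads_by = {"x": NanoporeRead("x", junk)}
        clusters = [Cluster(cluster_id="c", seed_umi="",
                            member_read_ids=["x"])]
        assignment = demultiplex(clusters, reads_by, barcodes,
                                 strand_by_read={"x": "+"})
        assert assignment.round_of("c") is None


class TestDedupeVariants:
    def test_identical_mutation_sets_collapse(self, ref):
        mut = MutationCall(position=190, kind="substitution",
                           ref_allele="C", alt_allele="A")
        res = [ConsensusResult(f"c{i}", [], frozenset({mut}), 20, 20)
               for i in range(2)]
        records = dedupe_variants({1: res}, ref)
        assert len(records) == 1
        assert records[0].round_counts == {1: 2}
        assert records[0].aa_mutations == aaset("A64E")

    def test_zero_clusters(self, ref):
        assert dedupe_variants({}, ref) == []

    def test_wild_type_is_empty_set_record(self, ref):
        res = [ConsensusResult("c0", [], frozenset(), 20, 20)]
        records = dedupe_variants({0: res}, ref)
        assert records[0].nt_mutations == frozenset()
        assert records[0].aa_mutations == frozenset()

    def test_simulated_pipeline_matches_truthside_dedup(self, ref, small_run):
        templates, reads, cfg = small_run
        exts = [e for e in (extract_umi(r, cfg.probe, cfg.umi_length)
                            for r in reads) if e.ok]
        clusters = cluster_greedy(exts, ScoringParams(threshold=20))
        by_id = {r.read_id: r for r in reads}
        results = [call_cluster([by_id[rid] for rid in cl.member_read_ids],
                                ref, cluster_id=cl.cluster_id)
                   for cl in clusters if len(cl) >= 15]
        records = dedupe_variants({0: results}, ref)
        truth_sets = {t.true_mutations for t in templates}
        assert {r.nt_mutations for r in records} == truth_sets
        assert len(records) == len(truth_sets)


class TestVariantDistance:
    def test_worked_examples(self):
        a = record("a", "A64E", "R102S")
        b = record("b", "A64E", "R102S", "E323V")
        assert variant_distance(a, a) == 0
        assert variant_distance(a, b) == 1

    def test_matches_symmetric_difference_oracle_and_is_metric(self):
        rng = np.random.default_rng(60)
        pool = [aa(f"{r}{i}{al}") for i, (r, al) in enumerate(
            zip("ARNDCEQGHILKMFPSTWYV", "VYWTSPFMKLIHGQECDNRA"), start=1)]
        recs = []
        for i in range(12):
            picks = rng.choice(20, size=int(rng.integers(0, 6)), replace=False)
            recs.append(VariantRecord(
                variant_id=f"v{i}", nt_mutations=frozenset(),
                aa_mutations=frozenset(pool[int(p)] for p in picks)))
        for x in recs:
            assert variant_distance(x, x) == 0
            for y in recs:
                d = variant_distance(x, y)
                assert d == len(set(x.aa_mutations) ^ set(y.aa_mutations))
                assert d == variant_distance(y, x)
                for z in recs:
                    assert d <= variant_distance(x, z) + variant_distance(z, y)


class TestBuildNetwork:
    def test_single_record(self):
        net = build_network([record("a", "A64E")])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_chain_at_dmax_one(self):
        wt = record("wt")
        one = record("one", "A64E")
        two = record("two", "A64E", "R102S")
        net = build_network([wt, one, two], d_max=1)
        assert set(map(frozenset, net.graph.edges)) == \
            {frozenset({"wt", "one"}), frozenset({"one", "two"})}

    def test_planted_lineages_recovered_as_components(self):
        rng = np.random.default_rng(61)
        founders = [aaset("A64E", "R102S"), aaset("E323V"),
                    aaset("D308V", "K7E")]
        records_ = []
        extra_pool = [aa(f"L{i}F") for i in range(400, 460)]
        for f_idx, core in enumerate(founders):
            for j in range(20):
                extras = rng.choice(60, size=int(rng.integers(0, 2)),
                                    replace=False)
                records_.append(VariantRecord(
                    variant_id=f"f{f_idx}_{j}", nt_mutations=frozenset(),
                    aa_mutations=core | {extra_pool[int(e)] for e in extras},
                    round_counts={1: 1}))
        net = build_network(records_, d_max=2)
        comps = net.components()
        assert len(comps) == 3
        got_cores = {frozenset.intersection(*(m.aa_mutations for m in comp))
                     for comp in comps}
        assert got_cores == set(founders)

    def test_embedding_is_deterministic(self):
        records_ = [record(f"v{i}", f"A{i+1}V") for i in range(10)]
        a = build_network(records_, embed=True, seed=7)
        b = build_network(records_, embed=True, seed=7)
        assert a.coords == b.coords
        assert set(a.coords) == {f"v{i}" for i in range(10)}


class TestFindFounders:
    def test_published_worked_example(self):
        members = [record("a", "A64E", "R102S"),
                   record("b", "A64E", "R102S", "E323V"),
                   record("c", "A64E", "R102S", "D308V")]
        founder, = find_founders([members])
        assert founder.core == aaset("A64E", "R102S")
        acquisitions = {frozenset(s.core - founder.core)
                        for s in founder.sub_lineages}
        assert acquisitions == {aaset("E323V"), aaset("D308V")}

    def test_singleton_cluster(self):
        founder, = find_founders([[record("a", "A64E")]])
        assert founder.core == aaset("A64E")

    def test_cluster_containing_wild_type_has_empty_core(self):
        members = [record("wt"), record("a", "A64E")]
        founder, = find_founders([members])
        assert founder.core == frozenset()

    def test_core_is_subset_of_every_member(self):
        rng = np.random.default_rng(62)
        pool = [aa(f"G{i}S") for i in range(1, 40)]
        members = []
        base = {pool[0], pool[1]}
        for i in range(15):
            extra = {pool[int(j)] for j in rng.integers(2, 39, rng.integers(0, 4))}
            members.append(VariantRecord(
                variant_id=f"m{i}", nt_mutations=frozenset(),
                aa_mutations=frozenset(base | extra)))
        founder, = find_founders([members])
        for m in members:
            assert founder.core <= m.aa_mutations

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            find_founders([[]])


class TestPositionalEnrichment:
    def _records(self, scale=1):
        # residue 64 mutated in 2/100 of round-1 counts, 10/100 of round-2,
        # every variant persisting into round 3
        recs = [
            record("hot", "A64E", rounds={1: 2 * scale, 2: 10 * scale, 3: 1}),
            record("flat", "R102S", rounds={1: 10 * scale, 2: 10 * scale, 3: 1}),
            record("wt_like", "K7E", rounds={1: 88 * scale, 2: 80 * scale, 3: 1}),
        ]
        return recs

    def test_hand_computed_factor(self):
        # f1 = 2/100, f2 = 10/100, eps = 1/200 -> 0.105 / 0.025 = 4.2
        table = positional_enrichment(self._records())
        assert table[64] == pytest.approx(4.2)

    def test_equal_frequencies_give_unity(self):
        table = positional_enrichment(self._records())
        assert table[102] == pytest.approx(1.0)

    def test_absent_in_round1_is_finite_and_enriched(self):
        recs = [record("new", "E323V", rounds={2: 5, 3: 1}),
                record("rest", "K7E", rounds={1: 95, 2: 90, 3: 1})]
        table = positional_enrichment(recs)
        assert 1 < table[323] < float("inf")

    def test_invariant_under_uniform_count_rescaling(self):
        # frequencies are fractions, so at fixed pseudocount the factors do
        # not depend on the overall sequencing depth
        a = positional_enrichment(self._records(scale=1), eps=0.005)
        b = positional_enrichment(self._records(scale=7), eps=0.005)
        for res in a:
            assert a[res] == pytest.approx(b[res])

    def test_nonpersistent_variants_excluded(self):
        recs = self._records() + [
            record("dropout", "W9C", rounds={1: 50, 2: 50})]
        table = positional_enrichment(recs)
        assert 9 not in table

    def test_missing_round_errors(self):
        recs = [record("only2", "A64E", rounds={2: 5, 3: 1})]
        with pytest.raises(ValueError, match="round 1"):
            positional_enrichment(recs)


class TestClassifyEpistasis:
    def _activities(self, alone, alone_ci, combo, combo_ci, bg_act=1.0):
        m = aa("E323V")
        bg = aaset("A64E", "R102S")
        return {
            frozenset(): ActivityRecord(frozenset(), 1.0, 0.0),
            frozenset({m}): ActivityRecord(frozenset({m}), alone, alone_ci),
            bg: ActivityRecord(bg, bg_act, 0.0),
            bg | {m}: ActivityRecord(bg | {m}, combo * bg_act, combo_ci * bg_act),
        }, m, bg

    def test_measured_sign_epistasis_case(self):
        # deleterious alone (15.7 +/- 1.1% of parent), beneficial in the
        # A64E R102S background (154 +/- 33% of that variant)
        acts, m, bg = self._activities(0.157, 0.011, 1.54, 0.33)
        call = classify_epistasis(acts, m, bg)
        assert call.kind == "sign"
        assert call.effect_alone == pytest.approx(0.157)
        assert call.effect_in_background == pytest.approx(1.54)

    def test_multiplicative_effects_are_none(self):
        acts, m, bg = self._activities(2.0, 0.0, 2.0, 0.0)
        assert classify_epistasis(acts, m, bg).kind == "none"

    def test_magnitude_epistasis(self):
        acts, m, bg = self._activities(2.0, 0.0, 1.2, 0.0)
        assert classify_epistasis(acts, m, bg).kind == "magnitude"

    def test_sign_requires_ci_exclusion_of_unity(self):
        # opposite signs but the background effect's CI includes 1
        acts, m, bg = self._activities(0.157, 0.011, 1.2, 0.5)
        assert classify_epistasis(acts, m, bg).kind == "none"

    def test_zero_background_activity_flagged(self):
        acts, m, bg = self._activities(0.5, 0.0, 1.5, 0.0)
        acts[bg] = ActivityRecord(bg, 0.0, 0.0)
        acts[bg | {m}] = ActivityRecord(bg | {m}, 0.5, 0.0)
        assert classify_epistasis(acts, m, bg).kind == "undefined"

    def test_symmetric_in_pairwise_case(self):
        a, b = aa("A64E"), aa("E323V")
        acts = {
            frozenset(): ActivityRecord(frozenset(), 1.0, 0.0),
            frozenset({a}): ActivityRecord(frozenset({a}), 2.0, 0.0),
            frozenset({b}): ActivityRecord(frozenset({b}), 0.4, 0.01),
            frozenset({a, b}): ActivityRecord(frozenset({a, b}), 3.0, 0.01),
        }
        ab = classify_epistasis(acts, b, frozenset({a}))
        ba = classify_epistasis(acts, a, frozenset({b}))
        assert ab.kind == ba.kind == "sign"

    def test_missing_record_raises(self):
        acts, m, bg = self._activities(0.5, 0.0, 1.5, 0.0)
        del acts[frozenset({m})]
        with pytest.raises(KeyError):
            classify_epistasis(acts, m, bg)
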