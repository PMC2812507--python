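"""Rearrangement simulator: operators, truth blocks, homology, evaluation."""

import pytest

from syntelign.model import ScoringParams
from syntelign.simulator import (
    SimHistory,
    TrueBlock,
    emit_homology,
    evaluate,
    evolve,
    extract_true_blocks,
    generate_ancestor,
    run_benchmark,
    run_pair,
    simulate_pair,
    verify_true_blocks,
)


class TestGenerateAncestor:
    def test_even_split_of_1040_genes(self):
        orders = generate_ancestor(1040, 2, seed=0)
        assert [len(o) for o in orders] == [520, 520]

    def test_one_gene_per_contig(self):
        orders = generate_ancestor(4, 4, seed=0)
        assert [len(o) for o in orders] == [1, 1, 1, 1]

    def test_deterministic_given_seed(self):
        a = generate_ancestor(50, 3, seed=7)
        b = generate_ancestor(50, 3, seed=7)
        assert [(g.gene_id, g.strand) for o in a for g in o.genes] == \
               [(g.gene_id, g.strand) for o in b for g in o.genes]

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_ancestor(2, 3, seed=0)


class TestEvolve:
    def test_zero_events_is_identity(self):
        anc = generate_ancestor(30, 2, seed=1)
        out, events = evolve(anc, 0, seed=1)
        assert events == []
        assert [(g.gene_id, g.strand) for o in out for g in o.genes] == \
               [(g.gene_id, g.strand) for o in anc for g in o.genes]

    def test_single_inversion_reverses_run_and_flips_strands(self):
        anc = generate_ancestor(30, 1, seed=2)
        out, events = evolve(anc, 1, size_range=(3, 3),
                             kind_weights={"inversion": 1.0}, seed=5)
        (ev,) = events
        assert ev.kind == "inversion" and ev.source[2] == 3
        s = ev.source[1]
        before = anc[0].genes
        after = out[0].genes
        for k in range(3):
            b = before[s + k]
            a = after[s + 2 - k]
            assert a.gene_id == b.gene_id and a.strand == -b.strand
        for k in list(range(s)) + list(range(s + 3, 30)):
            assert after[k].gene_id == before[k].gene_id
            assert after[k].strand == before[k].strand

    def test_gene_conservation_audit(self):
        """descendant gene count = ancestor + duplicated - deleted genes."""
        for seed in range(20):
            h = simulate_pair(n_genes=300, n_contigs=2, n_events=10, seed=seed)
            for orders, events in zip(h.descendants, h.events):
                dup = sum(e.source[2] for e in events if e.kind == "duplication")
                dele = sum(e.source[2] for e in events if e.kind == "deletion")
                assert sum(len(o) for o in orders) == 300 + dup - dele

    def test_no_gene_in_two_events(self):
        """Every gene id appears in at most one event's source run (both
        branches combined; family identity tracks ancestral genes)."""
        h = simulate_pair(n_genes=400, n_contigs=2, n_events=15, seed=3)
        # reconstruct touched families from descendant/ancestor divergence is
        # indirect; instead assert the structural consequence: truth blocks
        # are consistent and the verifier passes
        verify_true_blocks(h, extract_true_blocks(h))


class TestTrueBlocks:
    def test_zero_events_gives_one_block_per_contig(self):
        h = simulate_pair(n_genes=40, n_contigs=2, n_events=0, seed=1)
        blocks = extract_true_blocks(h)
        assert len(blocks) == 2
        assert sorted(len(b) for b in blocks) == [20, 20]
        verify_true_blocks(h, blocks)

    def test_single_interior_inversion_gives_three_blocks(self):
        h = _forced_history(kind="inversion")
        blocks = extract_true_blocks(h)
        assert len(blocks) == 3
        verify_true_blocks(h, blocks)
        ev = h.events[1][0]
        sizes = sorted(len(b) for b in blocks)
        assert ev.source[2] in sizes

    def test_deletion_splits_flanks_and_drops_genes(self):
        h = _forced_history(kind="deletion")
        blocks = extract_true_blocks(h)
        assert len(blocks) == 2
        verify_true_blocks(h, blocks)
        ev = h.events[1][0]
        s, size = ev.source[1], ev.source[2]
        deleted = {f"S2.g{idx:04d}" for idx in range(s, s + size)}
        covered = set().union(*(b.gene_ids for b in blocks))
        assert not (deleted & covered)

    def test_duplication_creates_paralog_block(self):
        h = _forced_history(kind="duplication")
        blocks = extract_true_blocks(h)
        verify_true_blocks(h, blocks)
        copy_blocks = [
            b for b in blocks
            if any(".c" in x or ".c" in y for x, y in b.pairs)
        ]
        assert len(copy_blocks) == 1
        assert len(copy_blocks[0]) == h.events[1][0].source[2]

    def test_verifier_passes_on_replicates(self):
        for seed in range(15):
            h = simulate_pair(n_genes=260, n_contigs=2, n_events=12, seed=seed)
            blocks = extract_true_blocks(h)
            verify_true_blocks(h, blocks)
            assert min(len(b) for b in blocks) >= 2

    def test_verifier_rejects_corrupted_blocks(self):
        h = simulate_pair(n_genes=60, n_contigs=1, n_events=2, seed=4)
        blocks = extract_true_blocks(h)
        broken = [TrueBlock(list(reversed(blocks[0].pairs)))] + blocks[1:]
        with pytest.raises(AssertionError):
            verify_true_blocks(h, broken)


def _forced_history(kind: str) -> SimHistory:
    """One event of the given kind on branch 2 only (branch 1 untouched)."""
    for seed in range(100):
        h = simulate_pair(n_genes=60, n_contigs=1, n_events=0, seed=seed)
        # evolve branch 2 manually with a single forced event
        anc = h.ancestor
        d2, events = evolve(
            [_respeciate(o, "S2") for o in anc], 1, size_range=(4, 4),
            kind_weights={kind: 1.0}, seed=seed,
        )
        ev = events[0]
        s, size = ev.source[1], ev.source[2]
        interior = 0 < s and s + size < 60
        if kind == "duplication":
            interior = True
        if interior:
            d1 = [_respeciate(o, "S1") for o in anc]
            fam = {g.gene_id: int(g.gene_id.split("g")[-1].split(".")[0])
                   for orders in (d1, d2) for o in orders for g in o.genes}
            return SimHistory(ancestor=anc, species=("S1", "S2"),
                              events=([], events), descendants=(d1, d2),
                              family_of=fam)
    raise RuntimeError("no interior event found")


def _respeciate(order, species):
    from syntelign.model import Gene, GeneOrder

    genes = [
        Gene(gene_id=f"{species}.g{int(g.gene_id.split('g')[-1]):04d}",
             species=species, contig=g.contig, start=g.start, end=g.end,
             strand=g.strand, rank=g.rank)
        for g in order.genes
    ]
    return GeneOrder(species=species, contig=order.contig, genes=genes)


class TestHomologyEmission:
    def test_self_and_family_scores(self):
        h = simulate_pair(n_genes=30, n_contigs=1, n_events=0, seed=0)
        t = emit_homology(h)
        g1 = h.descendants[0][0].genes[0].gene_id
        g2 = h.descendants[1][0].genes[0].gene_id
        assert t.get(g1, g1) == 1000.0
        assert t.get(g1, g2) == 500.0
        # singleton family: nothing beyond self + its ortholog partner
        others = [x for (a, b), _ in t.items() for x in (a, b)
                  if g1 in (a, b) and (a, b) != (g1, g1)]
        assert set(others) <= {g1, g2}

    def test_duplicated_family_fully_connected(self):
        h = _forced_history("duplication")
        t = emit_homology(h)
        blocks = extract_true_blocks(h)
        copies = [x for b in blocks for x, y in b.pairs if ".c" in x]
        copies += [y for b in blocks for x, y in b.pairs if ".c" in y]
        c = copies[0]
        fam = h.family_of[c.split(".c")[0].replace("S2", "S1")]
        members = [g for g, f in h.family_of.items() if f == fam]
        assert len(members) == 3
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                assert t.get(a, b) == 500.0


class _StubAlignment:
    def __init__(self, genes):
        self._genes = frozenset(genes)

    def aligned_gene_ids(self):
        return self._genes


class TestEvaluate:
    def _blocks(self):
        return [TrueBlock([("x1", "y1"), ("x2", "y2")]),
                TrueBlock([("x3", "y3"), ("x4", "y4"), ("x5", "y5")])]

    def test_exact_predictions_are_perfect(self):
        blocks = self._blocks()
        preds = [_StubAlignment(b.gene_ids) for b in blocks]
        assert evaluate(preds, blocks) == (1.0, 1.0)

    def test_empty_predictions(self):
        assert evaluate([], self._blocks()) == (0.0, 1.0)

    def test_partial_block_not_recovered_but_specific(self):
        blocks = self._blocks()
        preds = [_StubAlignment({"x3", "y3", "x4", "y4"})]  # misses x5/y5
        sens, spec = evaluate(preds, blocks)
        assert sens == 0.0
        assert spec == 1.0

    def test_off_block_genes_reduce_specificity(self):
        blocks = self._blocks()
        preds = [_StubAlignment({"x1", "y1", "x2", "y2", "junk"})]
        sens, spec = evaluate(preds, blocks)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(4 / 5)

    def test_block_split_across_alignments_not_recovered(self):
        blocks = self._blocks()
        preds = [_StubAlignment({"x1", "y1"}), _StubAlignment({"x2", "y2"})]
        sens, spec = evaluate(preds, blocks)
        assert sens == 0.0 and spec == 1.0


class TestBenchmark:
    def test_zero_event_pair_is_perfect_single_cell(self):
        df = run_benchmark(n_replicates=1, gap_values=(1.0,),
                           mismatch_values=(1.0,), seed=5, n_genes=60,
                           n_contigs=2, n_events=0)
        assert len(df) == 1
        assert df.sensitivity.iloc[0] == 1.0
        assert df.specificity.iloc[0] == 1.0

    def test_benchmark_deterministic_given_seed(self):
        kw = dict(n_replicates=2, gap_values=(0.5, 20.0),
                  mismatch_values=(1.0,), seed=9, n_genes=120, n_contigs=2,
                  n_events=4)
        assert run_benchmark(**kw).equals(run_benchmark(**kw))

    def test_perfect_conservation_identity(self):
        """Zero-event simulation: root CSMs cover every gene; (1.0, 1.0)."""
        h = simulate_pair(n_genes=80, n_contigs=2, n_events=0, seed=2)
        blocks = extract_true_blocks(h)
        csms = run_pair(h, ScoringParams(min_score=1.0))
        assert evaluate(csms, blocks) == (1.0, 1.0)
        covered = set().union(*(al.gene_ids() for al in csms))
        all_genes = {g.gene_id for orders in h.descendants
                     for o in orders for g in o.genes}
        assert covered == all_genes
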