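import pytest

from orannot.core import AlignmentHit, AnnotatorConfig, ExonSegment, GeneModel, Locus
from orannot.model_building import (
    chain_fragments,
    collect_best_query_hits,
    congruent,
    resolve_overlap,
    select_best_per_island,
    stitch,
)
from orannot.simulate import (
    SimulationConfig,
    emit_alignments,
    generate_genome,
    make_fragment_pair,
)
from orannot.io_formats import parse_exonerate

CFG = AnnotatorConfig()


def _hit(hid, query, span_t, span_q, strand="+", score=100.0, scaffold="s"):
    return AlignmentHit(
        hit_id=hid, query_id=query, query_span=span_q, target_id=scaffold,
        target_span=span_t, strand=strand, score=score,
        segments=[ExonSegment(target=span_t, query=span_q)],
    )


class TestBestPerIsland:
    def _locus(self, hits):
        return Locus("s", (0, 100), [h.hit_id for h in hits])

    def test_single_hit(self):
        h = _hit("a", "q1", (0, 30), (1, 10))
        best, query = select_best_per_island(self._locus([h]), {"a": h})
        assert best is h and query == "q1"

    def test_max_score_wins(self):
        h1 = _hit("a", "q1", (0, 30), (1, 10), score=700)
        h2 = _hit("b", "q2", (0, 30), (1, 10), score=500)
        best, _ = select_best_per_island(self._locus([h1, h2]), {"a": h1, "b": h2})
        assert best is h1

    def test_tie_breaks_lexicographic_then_leftmost(self):
        h1 = _hit("a", "qB", (0, 30), (1, 10), score=700)
        h2 = _hit("b", "qA", (10, 40), (1, 10), score=700)
        h3 = _hit("c", "qA", (5, 35), (1, 10), score=700)
        best, query = select_best_per_island(
            self._locus([h1, h2, h3]), {"a": h1, "b": h2, "c": h3}
        )
        assert query == "qA" and best is h3


class TestCollectAndCongruence:
    def test_collect_sorted_by_position(self):
        hits = [
            _hit("a", "q1", (500, 600), (30, 60)),
            _hit("b", "q1", (0, 100), (1, 25)),
            _hit("c", "q2", (200, 300), (1, 25)),
            _hit("d", "q1", (200, 300), (20, 40), scaffold="other"),
        ]
        got = collect_best_query_hits("q1", "s", hits)
        assert [h.hit_id for h in got] == ["b", "a"]

    def test_congruent_plus_strand(self):
        a = _hit("a", "q", (0, 180), (1, 60))
        b = _hit("b", "q", (400, 690), (55, 150))
        assert congruent(a, b)
        assert congruent(b, a)  # order-insensitive

    def test_query_order_reversed_not_congruent(self):
        a = _hit("a", "q", (0, 180), (55, 150))
        b = _hit("b", "q", (400, 690), (1, 60))
        assert not congruent(a, b)

    def test_opposite_strands_not_congruent(self):
        a = _hit("a", "q", (0, 180), (1, 60))
        b = _hit("b", "q", (400, 690), (55, 150), strand="-")
        assert not congruent(a, b)

    def test_nested_query_spans_not_congruent(self):
        a = _hit("a", "q", (0, 180), (1, 60))
        b = _hit("b", "q", (400, 500), (10, 40))
        assert not congruent(a, b)

    def test_minus_strand_congruence_runs_right_to_left(self):
        a = _hit("a", "q", (400, 690), (1, 60), strand="-")
        b = _hit("b", "q", (0, 180), (55, 150), strand="-")
        assert congruent(a, b)
        chains = chain_fragments([a, b])
        assert len(chains) == 1
        assert [h.hit_id for h in chains[0]] == ["a", "b"]


class TestStitch:
    def test_worked_example_six_aa_eighteen_nt(self):
        """Fragments at residues 5-50 and 45-150 overlap by 6 aa; the splice
        enumeration window is 18 nt and the unique gt..ag candidate is the
        implanted intron."""
        genome, protein, frags, intron = make_fragment_pair(seed=0)
        (model,) = stitch(frags, genome["scaf1"], protein, CFG)
        (j,) = model.junctions
        assert j.overlap_aa == 6
        assert j.window_nt == 18
        assert j.n_candidates == 1
        assert j.intron == intron

    def test_no_overlap_direct_concatenation(self):
        genome, protein, frags, intron = make_fragment_pair(
            seed=1, frag1_span=(5, 47), frag2_span=(48, 150)
        )
        (model,) = stitch(frags, genome["scaf1"], protein, CFG)
        (j,) = model.junctions
        assert j.overlap_aa == 0 and j.window_nt == 0 and j.donor_offset is None

    def test_single_fragment_unchanged(self):
        genome, protein, frags, _ = make_fragment_pair(seed=2)
        (model,) = stitch(frags[:1], genome["scaf1"], protein, CFG)
        assert model.exons == [frags[0].segments[0].target]
        assert model.junctions == []

    def test_unstitchable_junction_splits_model(self):
        genome, protein, frags, intron = make_fragment_pair(seed=3)
        # destroy the donor site so no gt..ag candidate exists
        seq = genome["scaf1"]
        window = seq[intron[0] - 9 : intron[0] + 11].replace("G", "A").replace("g", "a")
        genome.sequences["scaf1"] = seq[: intron[0] - 9] + window + seq[intron[0] + 11 :]
        models = stitch(frags, genome.sequences["scaf1"], protein, CFG)
        assert len(models) == 2
        assert all("unstitched_junction" in m.flags for m in models)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_simulated_fragmented_genes_recover_true_introns(self, seed):
        config = SimulationConfig(seed=seed, n_scaffolds=2, genes_per_scaffold=3,
                                  fraction_fragmented=1.0)
        ledger = generate_genome(config)
        hits = parse_exonerate(emit_alignments(ledger, config))
        genome = ledger.genome
        by_gene = {}
        for h in hits:
            by_gene.setdefault(h.query_id, []).append(h)
        for gene_id, frag in ledger.fragmentation.items():
            chains = chain_fragments(by_gene[gene_id])
            assert len(chains) == 1
            (model,) = stitch(
                chains[0], genome[chains[0][0].target_id],
                ledger.proteins[gene_id], CFG,
            )
            stitched = [j.intron for j in model.junctions if j.overlap_aa > 0]
            assert stitched == [frag.intron]
            # stitched exon chain equals ground truth
            truth = next(t for t in ledger.transcripts if t.gene_id == gene_id)
            truth_exons = list(truth.exons)
            got = sorted(model.exons)
            # alignment omits the terminal stop codon (3 nt of the last exon)
            if model.strand == "+":
                got[-1] = (got[-1][0], got[-1][1] + 3)
            else:
                got[0] = (got[0][0] - 3, got[0][1])
            assert got == truth_exons

    def test_every_stitched_junction_is_gt_ag(self):
        from orannot.core import revcomp

        config = SimulationConfig(seed=21, fraction_fragmented=1.0)
        ledger = generate_genome(config)
        hits = parse_exonerate(emit_alignments(ledger, config))
        by_gene = {}
        for h in hits:
            by_gene.setdefault(h.query_id, []).append(h)
        for gene_id in ledger.fragmentation:
            chains = chain_fragments(by_gene[gene_id])
            (model,) = stitch(
                chains[0], ledger.genome[chains[0][0].target_id],
                ledger.proteins[gene_id], CFG,
            )
            seq = ledger.genome[model.scaffold]
            for j in model.junctions:
                s, e = j.intron
                intron_seq = seq[s:e] if model.strand == "+" else revcomp(seq[s:e])
                assert intron_seq[:2].lower() == "gt"
                assert intron_seq[-2:].lower() == "ag"


def _gm(name, query, qspan, exons, complete="complete", pseudo=frozenset(),
        start=True, protein_len=320):
    return GeneModel(
        name=name, scaffold="s", strand="+", exons=exons, has_start=start,
        has_stop=True, pseudo_defects=set(pseudo), completeness=complete,
        provenance="P1", best_query_id=query, protein="M" * protein_len,
        cds="ATG" * protein_len, query_span=qspan,
    )


class TestResolveOverlap:
    def test_disjoint_query_regions_keep_both(self):
        a = _gm("a", "q", (1, 100), [(0, 300)])
        b = _gm("b", "q", (120, 220), [(1000, 1300)])
        assert resolve_overlap(a, b, CFG) == "both"

    def test_overlap_just_below_threshold_keeps_both(self):
        a = _gm("a", "q", (1, 100), [(0, 300)])
        b = _gm("b", "q", (82, 181), [(400, 700)])  # 19 aa / 100 aa each
        assert resolve_overlap(a, b, CFG) == "both"

    def test_overlap_at_threshold_picks_winner(self):
        a = _gm("a", "q", (1, 100), [(0, 300)])
        b = _gm("b", "q", (81, 180), [(400, 700)])  # exactly 20 %
        assert resolve_overlap(a, b, CFG) in (a, b)

    def test_completeness_outranks_length(self):
        a = _gm("a", "q", (1, 100), [(0, 300)], complete="complete", protein_len=310)
        b = _gm("b", "q", (41, 140), [(200, 500)], complete="partial", protein_len=400)
        assert resolve_overlap(a, b, CFG) is a

    def test_non_pseudo_preferred_at_equal_length(self):
        a = _gm("a", "q", (1, 100), [(0, 300)], pseudo={"inframe_stop"})
        b = _gm("b", "q", (41, 140), [(200, 500)])
        assert resolve_overlap(a, b, CFG) is b
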