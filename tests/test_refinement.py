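import os
import stat
import sys
from pathlib import Path

import pytest

from orannot.core import AnnotatorConfig, GeneModel, SequenceSet, StitchedModel
from orannot.refinement import (
    ExternalRefiner,
    classify,
    extend_locus,
    finalize,
    merge_p1_p2,
    name_model,
)

CFG = AnnotatorConfig()


class TestExtendLocus:
    def test_clamped_at_scaffold_edges(self):
        assert extend_locus((0, 900), 1000, CFG) == (0, 1000)

    def test_extension_equals_hit_length_when_short(self):
        assert extend_locus((10000, 12000), 100000, CFG) == (8000, 14000)

    def test_extension_capped_at_6000(self):
        assert extend_locus((20000, 29000), 100000, CFG) == (14000, 35000)


def _stitched(exons, strand="+", scaffold="s1", defects=frozenset()):
    return StitchedModel(
        query_id="q", scaffold=scaffold, strand=strand, exons=exons,
        source_hit_ids=["h"], score=100.0, defects=set(defects),
        query_span=(1, sum(e - s for s, e in exons) // 3),
    )


class TestFinalize:
    def test_atg_at_origin_no_extension(self):
        cds = "ATG" + "GGT" * 20 + "TAA"
        genome = SequenceSet({"s1": "C" * 50 + cds + "C" * 50}, "nucleotide")
        model = _stitched([(50, 50 + len(cds))])
        gene = finalize(model, genome, CFG)
        assert gene.has_start and gene.has_stop
        assert gene.exons == [(50, 50 + len(cds))]
        assert gene.protein.endswith("*") and "*" not in gene.protein[:-1]

    def test_upstream_atg_extends_first_exon_by_exact_codons(self):
        """ATG 10 codons upstream (clean in-frame path) grows the first
        exon by exactly 30 nt."""
        body = "GGT" * 30
        upstream = "ATG" + "CCA" * 9  # ATG then 9 neutral codons
        genome = SequenceSet({"s1": "C" * 48 + upstream + body + "TAA" + "C" * 20},
                             "nucleotide")
        start = 48 + len(upstream)
        model = _stitched([(start, start + len(body))])
        gene = finalize(model, genome, CFG)
        assert gene.has_start
        assert gene.exons[0] == (start - 30, start + len(body) + 3)
        assert gene.protein.startswith("M")

    def test_intervening_stop_blocks_start_search(self):
        body = "GGT" * 30
        upstream = "ATG" + "TAA" + "CCA" * 8  # stop between ATG and gene
        genome = SequenceSet({"s1": "C" * 48 + upstream + body + "TAA" + "C" * 20},
                             "nucleotide")
        start = 48 + len(upstream)
        gene = finalize(_stitched([(start, start + len(body))]), genome, CFG)
        assert not gene.has_start

    def test_downstream_stop_extends_last_exon(self):
        body = "ATG" + "GGT" * 30
        genome = SequenceSet({"s1": "C" * 30 + body + "CCAGAC" + "TGA" + "C" * 20},
                             "nucleotide")
        gene = finalize(_stitched([(30, 30 + len(body))]), genome, CFG)
        assert gene.has_stop
        assert gene.exons[0][1] == 30 + len(body) + 9

    def test_internal_tga_flags_pseudogene(self):
        cds = "ATG" + "GGT" * 10 + "TGA" + "GGT" * 10 + "TAA"
        genome = SequenceSet({"s1": "C" * 30 + cds + "C" * 30}, "nucleotide")
        gene = finalize(_stitched([(30, 30 + len(cds))]), genome, CFG)
        assert "inframe_stop" in gene.pseudo_defects
        assert "*" in gene.protein[:-1]

    def test_non_codon_length_flags_frameshift(self):
        cds = "ATG" + "GGT" * 10 + "GG" + "GGT" * 10
        genome = SequenceSet({"s1": "C" * 30 + cds + "C" * 30}, "nucleotide")
        gene = finalize(_stitched([(30, 30 + len(cds))]), genome, CFG)
        assert "frameshift" in gene.pseudo_defects

    def test_minus_strand_start_stop(self):
        from orannot.core import revcomp

        cds = "ATG" + "GGT" * 25 + "TAA"
        fwd = "C" * 40 + revcomp(cds) + "C" * 40
        genome = SequenceSet({"s1": fwd}, "nucleotide")
        iv = (40, 40 + len(cds))
        gene = finalize(_stitched([iv], strand="-"), genome, CFG)
        assert gene.has_start and gene.has_stop
        assert gene.protein[0] == "M" and gene.protein.endswith("*")

    def test_finalization_never_shortens(self):
        cds = "GGT" * 40
        genome = SequenceSet({"s1": "C" * 30 + cds + "C" * 30}, "nucleotide")
        gene = finalize(_stitched([(30, 30 + len(cds))]), genome, CFG)
        assert gene.exons[0][0] <= 30 and gene.exons[0][1] >= 30 + len(cds)


def _gene(protein_len, complete=None, pseudo=frozenset(), start=True,
          provenance="P1", exons=((0, 100),)):
    g = GeneModel(
        name="", scaffold="s1", strand="+", exons=list(exons), has_start=start,
        has_stop=True, pseudo_defects=set(pseudo), completeness="partial",
        provenance=provenance, best_query_id="q", protein="M" * protein_len,
        cds="ATG" * protein_len,
    )
    g.completeness = complete or classify(g, CFG)
    return g


class TestClassify:
    def test_default_cutoff_boundary(self):
        assert classify(_gene(300), CFG) == "complete"
        assert classify(_gene(299), CFG) == "partial"

    def test_terminal_stop_excluded_from_length(self):
        g = _gene(300)
        g.protein = "M" * 299 + "*"
        assert classify(g, CFG) == "partial"

    def test_overridden_cutoff(self):
        cfg = AnnotatorConfig(min_complete_len=100)
        assert classify(_gene(150), cfg) == "complete"

    def test_monotone_in_protein_length(self):
        labels = [classify(_gene(n), CFG) for n in range(295, 306)]
        flip = labels.index("complete")
        assert all(l == "partial" for l in labels[:flip])
        assert all(l == "complete" for l in labels[flip:])


class TestMergeP1P2:
    def test_absent_p2(self):
        p1 = _gene(320)
        assert merge_p1_p2(p1, None) == [p1]

    def test_identical_structures_keep_one(self):
        out = merge_p1_p2(_gene(320), _gene(320, provenance="P2"))
        assert len(out) == 1
        assert out[0].provenance == "merged"

    def test_clean_p2_beats_pseudo_p1(self):
        p1 = _gene(320, pseudo={"inframe_stop"})
        p2 = _gene(320, provenance="P2")
        (winner,) = merge_p1_p2(p1, p2)
        assert winner.best_query_id == p2.best_query_id and not winner.pseudo_defects

    def test_disjoint_keeps_both(self):
        p1 = _gene(320, exons=((0, 100),))
        p2 = _gene(320, provenance="P2", exons=((500, 600),))
        assert len(merge_p1_p2(p1, p2)) == 2


class TestNaming:
    def test_flag_suffixes(self):
        g = _gene(100, start=False, pseudo={"frameshift"}, exons=((99, 400),))
        assert name_model(g, 3) == "s1:100-400(+)OR3-NTE-PSE-P"

    def test_clean_complete_name(self):
        g = _gene(320, exons=((0, 963),))
        assert name_model(g, 1) == "s1:1-963(+)OR1"


def _stub_refiner(tmp_path: Path, body: str) -> str:
    script = tmp_path / "refiner.py"
    script.write_text(f"#!{sys.executable}\nimport sys\n{body}\n")
    script.chmod(script.stat().st_mode | stat.S_IEXEC)
    return str(script)


class TestExternalRefiner:
    def test_unavailable_refiner_degrades_gracefully(self, tmp_path):
        refiner = ExternalRefiner(str(tmp_path / "missing-exe"))
        genome = SequenceSet({"s1": "ACGT" * 100}, "nucleotide")
        with pytest.warns(Warning, match="refiner"):
            out = refiner.refine(genome, "s1", (0, 400), "q", "MKT")
        assert out is None

    def test_stub_rows_lifted_to_scaffold_coordinates(self, tmp_path):
        body = 'print("slice\\tstub\\tcds\\t11\\t40\\t.\\t+\\t.\\tID=x")'
        refiner = ExternalRefiner(_stub_refiner(tmp_path, body))
        genome = SequenceSet({"s1": "ACGT" * 200}, "nucleotide")
        model = refiner.refine(genome, "s1", (100, 500), "q", "MKT")
        assert model is not None
        assert model.exons == [(110, 140)]

    def test_nonzero_exit_yields_no_p2(self, tmp_path):
        refiner = ExternalRefiner(_stub_refiner(tmp_path, "sys.exit(3)"))
        genome = SequenceSet({"s1": "ACGT" * 100}, "nucleotide")
        with pytest.warns(Warning, match="status 3"):
            assert refiner.refine(genome, "s1", (0, 400), "q", "MKT") is None
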