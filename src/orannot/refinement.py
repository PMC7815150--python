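"""Refinement and finalization of stitched gene models.

A preliminary (P1) model may be handed to an external gene-structure
predictor (a GeneWise-class tool) over an extended genomic window together
with its best query protein, yielding a P2 model; overlapping P1/P2 pairs
are resolved to the better model, disjoint ones are both kept.  The refiner
is optional — without it the pipeline runs P1-only.

Finalization searches for a START codon up to 20 codons upstream and a STOP
codon up to 20 codons downstream of the aligned region, translates the CDS,
flags pseudogenizing defects (in-frame stops, frameshifts), classifies the
model complete/partial against the length cutoff (default 300 aa), and
assigns a name encoding location, strand and status flags.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from pathlib import Path
from typing import Optional

from .core import (
    AnnotatorConfig,
    GeneModel,
    SequenceSet,
    StitchedModel,
    STOP_CODONS,
    revcomp,
)
from .io_formats import AnnotationWarning, translate_cds, write_fasta


def extend_locus(
    model_span: tuple[int, int], scaffold_length: int, config: AnnotatorConfig
) -> tuple[int, int]:
    """Extend a hit span on both sides by min(hit length, max_extension),
    clamped to the scaffold."""
    s, e = model_span
    ext = min(e - s, config.max_extension)
    return (max(0, s - ext), min(scaffold_length, e + ext))


class ExternalRefiner:
    """Subprocess adapter for an optional gene-structure refiner.

    Contract: ``exe <target_fasta> <query_fasta>`` prints GFF-style rows; the
    ``cds``/``exon`` rows (1-based, relative to the target slice) define the
    refined exon chain.  Any failure degrades gracefully to "no P2 model".
    """

    def __init__(self, exe: str):
        self.exe = exe

    def refine(
        self,
        genome: SequenceSet,
        scaffold: str,
        window: tuple[int, int],
        query_id: str,
        query_seq: str,
    ) -> Optional[StitchedModel]:
        s, e = window
        slice_seq = genome[scaffold][s:e]
        with tempfile.TemporaryDirectory() as tmp:
            target_fa = Path(tmp) / "target.fa"
            query_fa = Path(tmp) / "query.fa"
            target_fa.write_text(write_fasta([(f"{scaffold}:{s}-{e}", slice_seq)]))
            query_fa.write_text(write_fasta([(query_id, query_seq)]))
            try:
                proc = subprocess.run(
                    [self.exe, str(target_fa), str(query_fa)],
                    capture_output=True,
                    text=True,
                    timeout=300,
                )
            except (OSError, subprocess.TimeoutExpired) as exc:
                warnings.warn(f"refiner failed to run: {exc}", AnnotationWarning)
                return None
        if proc.returncode != 0:
            warnings.warn(
                f"refiner exited with status {proc.returncode}; P2 skipped",
                AnnotationWarning,
            )
            return None
        exons: list[tuple[int, int]] = []
        strand = "+"
        for line in proc.stdout.splitlines():
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2].lower() not in ("cds", "exon"):
                continue
            try:
                iv = (s + int(cols[3]) - 1, s + int(cols[4]))
            except ValueError:
                warnings.warn("unparsable refiner row skipped", AnnotationWarning)
                continue
            strand = cols[6]
            exons.append(iv)
        if not exons:
            warnings.warn("refiner produced no exon rows; P2 skipped", AnnotationWarning)
            return None
        exons.sort(reverse=(strand == "-"))
        return StitchedModel(
            query_id=query_id,
            scaffold=scaffold,
            strand=strand,
            exons=exons,
            source_hit_ids=[],
            score=0.0,
        )


def _ranking_key(model: GeneModel) -> tuple:
    return (
        model.completeness == "complete",
        model.protein_len,
        not model.is_pseudo,
        model.has_start,
    )


def _exonic_overlap(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def merge_p1_p2(p1: GeneModel, p2: Optional[GeneModel]) -> list[GeneModel]:
    """Keep the better of an overlapping P1/P2 pair, or both if disjoint.

    Overlap means shared exonic bases on the same strand.  Ranking:
    completeness, protein length, non-pseudogenous, START presence; exact
    ties go to the refined (P2) model.
    """
    if p2 is None:
        return [p1]
    if p1.strand == p2.strand and p1.scaffold == p2.scaffold and _exonic_overlap(p1, p2) > 0:
        winner = p2 if _ranking_key(p2) >= _ranking_key(p1) else p1
        winner.provenance = "merged"
        return [winner]
    return [p1, p2]


def finalize(
    model: StitchedModel,
    genome: SequenceSet,
    config: AnnotatorConfig,
    provenance: str = "P1",
) -> GeneModel:
    """Terminal-codon search, translation, defect flagging, classification.

    Finalization never shortens a model: the first exon may grow upstream to
    the nearest in-frame ATG (within the search window, no in-frame stop on
    the way) and the last exon may grow downstream through the first stop
    codon found in the window.
    """
    if not model.exons:
        raise ValueError("cannot finalize a model without exons")
    seq_fwd = genome[model.scaffold]
    length = len(seq_fwd)
    window = config.terminal_search_window

    # coding-strand coordinates: ascending transcription order
    if model.strand == "+":
        seq = seq_fwd
        exons = [list(iv) for iv in model.exons]
    else:
        seq = revcomp(seq_fwd)
        exons = [[length - e, length - s] for s, e in model.exons]
    exons.sort()

    def cds_text() -> str:
        return "".join(seq[s:e] for s, e in exons)

    cds = cds_text()
    has_start = cds[:3] == "ATG"
    if not has_start:
        first = exons[0][0]
        for i in range(1, window + 1):
            pos = first - 3 * i
            if pos < 0:
                break
            codon = cds_codon = seq[pos : pos + 3]
            if codon == "ATG":
                exons[0][0] = pos
                has_start = True
                break
            if cds_codon in STOP_CODONS:
                break

    cds = cds_text()
    has_stop = len(cds) % 3 == 0 and cds[-3:] in STOP_CODONS
    if not has_stop:
        last_end = exons[-1][1]
        for j in range(window):
            pos = last_end + 3 * j
            if pos + 3 > length:
                break  # STOP search never crosses a scaffold end
            if seq[pos : pos + 3] in STOP_CODONS:
                exons[-1][1] = pos + 3
                has_stop = True
                break

    cds = cds_text()
    protein = translate_cds(cds)
    defects = set()
    if "*" in protein[:-1]:
        defects.add("inframe_stop")
    if len(cds) % 3 != 0 or "frameshift" in model.defects:
        defects.add("frameshift")

    if model.strand == "+":
        fwd_exons = [(s, e) for s, e in exons]
    else:
        fwd_exons = [(length - e, length - s) for s, e in exons]

    gene = GeneModel(
        name="",
        scaffold=model.scaffold,
        strand=model.strand,
        exons=fwd_exons,
        has_start=has_start,
        has_stop=has_stop,
        pseudo_defects=defects,
        completeness="partial",
        provenance=provenance,
        best_query_id=model.query_id,
        protein=protein,
        cds=cds,
        score=model.score,
        junctions=list(model.junctions),
        flags=set(model.flags),
        query_span=model.query_span,
    )
    gene.completeness = classify(gene, config)
    return gene


def classify(model: GeneModel, config: AnnotatorConfig) -> str:
    """Complete iff the protein (excluding a terminal stop) reaches the
    completeness cutoff."""
    return "complete" if model.protein_len >= config.min_complete_len else "partial"


def name_model(model: GeneModel, serial: int) -> str:
    """``{scaffold}:{start}-{end}({strand})OR{serial}`` plus status suffixes
    (-NTE no start, -PSE pseudogenous, -P partial); coordinates 1-based."""
    s, e = model.span
    name = f"{model.scaffold}:{s + 1}-{e}({model.strand})OR{serial}"
    if not model.has_start:
        name += "-NTE"
    if model.is_pseudo:
        name += "-PSE"
    if model.completeness == "partial":
        name += "-P"
    return name
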