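"""Readers and writers for the pipeline's file formats.

Supported formats:

* Exonerate ``protein2genome`` output *with embedded GFF dumps* (the
  ``--showtargetgff yes`` form).  Only the GFF blocks are interpreted; the
  human-readable alignment text and ``vulgar:``/``cigar:`` lines are skipped.
  Files containing only vulgar/cigar records are rejected.
* FASTA (via Biopython).
* GFF3 gene annotations (gene/mRNA/exon-or-CDS hierarchy).
* Output: GFF3, BED12+1 (12 BED columns plus a status column), CDS and
  protein FASTA.

Accepted Exonerate-GFF grammar
------------------------------
Each alignment record contributes, between ``# --- START OF GFF DUMP ---``
and ``# --- END OF GFF DUMP ---`` markers, one ``gene`` row (score column
populated, ``sequence <query>`` attribute), one or more ``exon`` rows, and a
``similarity`` row whose attributes carry ``Align <target_start>
<query_start> <length>`` triples: *target_start* is the 1-based forward
coordinate of the segment's first base in transcription order (its highest
base for minus-strand records), *query_start* the 1-based aa position, and
*length* the segment length in nucleotides.
"""

from __future__ import annotations

import io
import re
import warnings
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .core import (
    AlignmentHit,
    ExonSegment,
    GeneModel,
    SequenceSet,
    TranscriptAnnotation,
)

GFF_SOURCE = "orannot"


class ParseError(ValueError):
    """Raised for malformed input, naming the offending line."""


class AnnotationWarning(UserWarning):
    """Non-fatal input problems (records skipped, features dropped)."""


def _as_handle(stream: Union[str, TextIO]) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def translate_cds(cds: str) -> str:
    """Translate a CDS, rendering in-frame stops as '*'.

    Trailing bases that do not fill a codon (frameshifted models) are
    dropped from the translation.
    """
    usable = len(cds) // 3 * 3
    if usable == 0:
        return ""
    return str(Seq(cds[:usable]).translate())


# ---------------------------------------------------------------------------
# Exonerate-with-GFF parsing
# ---------------------------------------------------------------------------

_ALIGN_RE = re.compile(r"Align\s+(\d+)\s+(\d+)\s+(\d+)")
_SEQUENCE_RE = re.compile(r"sequence\s+(\S+)")


def parse_exonerate(stream: Union[str, TextIO]) -> list[AlignmentHit]:
    """Parse Exonerate protein2genome output with embedded GFF blocks.

    Returns one :class:`AlignmentHit` per ``gene`` feature.  Minus-strand
    records are normalized so every target interval is expressed on the
    forward strand (start < end) while segment list order follows
    transcription order.
    """
    handle = _as_handle(stream)
    hits: list[AlignmentHit] = []
    in_gff = False
    saw_gff_dump = False
    saw_sugar_only = False
    current: dict | None = None
    serial = 0

    def finish(record: dict, lineno: int) -> None:
        nonlocal serial
        hit = _assemble_hit(record, serial, lineno)
        if hit is not None:
            hits.append(hit)
            serial += 1

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if "START OF GFF DUMP" in line:
            in_gff = True
            saw_gff_dump = True
            continue
        if "END OF GFF DUMP" in line:
            if current is not None:
                finish(current, lineno)
                current = None
            in_gff = False
            continue
        if not in_gff:
            if line.startswith(("vulgar:", "cigar:")):
                saw_sugar_only = True
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"line {lineno}: expected 9 GFF columns, got {len(cols)}")
        scaffold, _source, feature, start_s, end_s, score_s, strand, _frame, attrs = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        if feature == "gene":
            if current is not None:
                finish(current, lineno)
            m = _SEQUENCE_RE.search(attrs)
            if m is None:
                raise ParseError(f"line {lineno}: gene row lacks 'sequence' attribute")
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: gene row lacks a score") from exc
            current = {
                "scaffold": scaffold,
                "span": (start - 1, end),
                "strand": strand,
                "score": score,
                "query": m.group(1),
                "exons": [],
                "aligns": [],
                "lineno": lineno,
            }
        elif feature == "exon":
            if current is None:
                raise ParseError(f"line {lineno}: exon row outside a gene record")
            current["exons"].append(((start - 1, end), lineno))
        elif feature == "similarity":
            if current is None:
                raise ParseError(f"line {lineno}: similarity row outside a gene record")
            current["aligns"].extend(
                (int(t), int(q), int(n)) for t, q, n in _ALIGN_RE.findall(attrs)
            )
        # cds / intron / splice5 / splice3 / utr rows are ignored

    if current is not None:
        finish(current, 0)
    if not saw_gff_dump and saw_sugar_only:
        raise ParseError(
            "input contains only vulgar/cigar records; Exonerate must be run "
            "with --showtargetgff yes so GFF blocks are present"
        )
    return hits


def _assemble_hit(rec: dict, serial: int, lineno: int) -> AlignmentHit | None:
    scaffold = rec["scaffold"]
    gspan = rec["span"]
    strand = rec["strand"]
    # reject exons outside the gene span; skip the record but keep parsing
    for (es, ee), eln in rec["exons"]:
        if es < gspan[0] or ee > gspan[1]:
            warnings.warn(
                f"line {eln}: exon [{es + 1},{ee}] outside gene span; record skipped",
                AnnotationWarning,
            )
            return None
    if not rec["exons"]:
        warnings.warn(
            f"line {rec['lineno']}: gene record without exon rows skipped",
            AnnotationWarning,
        )
        return None

    exon_ivs = [iv for iv, _ in rec["exons"]]
    # transcription order: ascending for '+', descending for '-'
    exon_ivs.sort(key=lambda iv: iv[0], reverse=(strand == "-"))

    # map Align triples onto exons
    per_exon: list[list[tuple[int, int, int]]] = [[] for _ in exon_ivs]
    for t1, q1, n in rec["aligns"]:
        if strand == "-":
            fwd = (t1 - n, t1)  # t1 is the 1-based highest (first transcribed) base
        else:
            fwd = (t1 - 1, t1 - 1 + n)
        placed = False
        for i, iv in enumerate(exon_ivs):
            if fwd[0] >= iv[0] and fwd[1] <= iv[1]:
                per_exon[i].append((fwd[0], q1, n))
                placed = True
                break
        if not placed:
            warnings.warn(
                f"line {lineno or rec['lineno']}: Align triple outside exons; ignored",
                AnnotationWarning,
            )

    segments: list[ExonSegment] = []
    defects: set[str] = set()
    cum_nt = 0
    for iv, triples in zip(exon_ivs, per_exon):
        exon_len = iv[1] - iv[0]
        if triples:
            qstart = min(q for _, q, _ in triples)
            qend = max(q + n // 3 - 1 for _, q, n in triples)
            covered = sum(n for _, _, n in triples)
            frameshift = covered != exon_len or any(n % 3 for _, _, n in triples)
        else:
            # no per-segment query map: infer from cumulative arithmetic
            qstart = cum_nt // 3 + 1
            qend = (cum_nt + exon_len) // 3
            frameshift = False
        if frameshift:
            defects.add("frameshift")
        segments.append(
            ExonSegment(
                target=iv,
                query=(qstart, qend),
                phase=cum_nt % 3,
                frameshift=frameshift,
            )
        )
        cum_nt += exon_len

    qspan = (min(s.query[0] for s in segments), max(s.query[1] for s in segments))
    hit = AlignmentHit(
        hit_id=f"hit{serial}",
        query_id=rec["query"],
        query_span=qspan,
        target_id=scaffold,
        target_span=gspan,
        strand=strand,
        score=rec["score"],
        segments=segments,
        defects=defects,
    )
    hit.validate()
    return hit


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: Union[str, TextIO], alphabet: str) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`; ids are the first token."""
    handle = _as_handle(stream)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        if record.id in seqs:
            raise ParseError(f"duplicate FASTA id: {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            warnings.warn(f"empty sequence for {record.id}", AnnotationWarning)
        seqs[record.id] = seq
    return SequenceSet(sequences=seqs, alphabet=alphabet)


def write_fasta(seqs: Iterable[tuple[str, str]], width: int = 60) -> str:
    out: list[str] = []
    for name, seq in seqs:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
        if not seq:
            out.append("")
    return "\n".join(out) + "\n" if out else ""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff_transcripts(stream: Union[str, TextIO]) -> list[TranscriptAnnotation]:
    """Read a GFF3 annotation into per-mRNA transcripts.

    Exon children are preferred; if an mRNA has none, its CDS rows are used.
    Exonless transcripts and orphan exons are dropped with a warning.
    """
    handle = _as_handle(stream)
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    children: dict[str, dict[str, list[tuple[int, int]]]] = {}

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"line {lineno}: expected 9 GFF columns")
        scaffold, source, feature, start_s, end_s, _score, strand, _frame, attr_s = cols
        try:
            iv = (int(start_s) - 1, int(end_s))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        attrs = _parse_attrs(attr_s)
        ftype = feature.lower()
        if ftype in ("mrna", "transcript"):
            tid = attrs.get("ID", f"transcript{lineno}")
            mrnas[tid] = {
                "scaffold": scaffold,
                "strand": strand,
                "source": source,
                "gene": attrs.get("Parent", tid),
                "attrs": {k: v for k, v in attrs.items() if k not in ("ID", "Parent")},
            }
            order.append(tid)
        elif ftype in ("exon", "cds"):
            parent = attrs.get("Parent")
            if parent is None:
                warnings.warn(f"line {lineno}: orphan {feature} dropped", AnnotationWarning)
                continue
            for p in parent.split(","):
                children.setdefault(p, {}).setdefault(ftype, []).append(iv)

    transcripts: list[TranscriptAnnotation] = []
    for tid in order:
        info = mrnas[tid]
        kid = children.get(tid, {})
        exons = kid.get("exon") or kid.get("cds")
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; dropped", AnnotationWarning)
            continue
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=tid,
                gene_id=info["gene"],
                scaffold=info["scaffold"],
                strand=info["strand"],
                exons=sorted(exons),
                source=info["source"],
                attributes=info["attrs"],
            )
        )
    # orphan exons whose parent mRNA never appeared
    for parent in children:
        if parent not in mrnas:
            warnings.warn(f"exons with unknown parent {parent} dropped", AnnotationWarning)
    return transcripts


def write_transcripts_gff3(transcripts: list[TranscriptAnnotation]) -> str:
    """Write transcripts as a gene/mRNA/CDS GFF3 document (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        s, e = t.span
        base = (t.scaffold, t.source)
        attrs = "".join(f";{k}={v}" for k, v in sorted(t.attributes.items()))
        lines.append(
            "\t".join([*base, "gene", str(s + 1), str(e), ".", t.strand, ".", f"ID={t.gene_id}"])
        )
        lines.append(
            "\t".join(
                [*base, "mRNA", str(s + 1), str(e), ".", t.strand, ".",
                 f"ID={t.transcript_id};Parent={t.gene_id}{attrs}"]
            )
        )
        # CDS rows in transcription order with GFF phase
        exons = t.exons if t.strand == "+" else sorted(t.exons, reverse=True)
        cum = 0
        cds_rows = []
        for (xs, xe) in exons:
            phase = (3 - cum % 3) % 3
            cds_rows.append(
                "\t".join(
                    [*base, "CDS", str(xs + 1), str(xe), ".", t.strand, str(phase),
                     f"ID={t.transcript_id}.cds;Parent={t.transcript_id}"]
                )
            )
            cum += xe - xs
        lines.extend(cds_rows if t.strand == "+" else cds_rows[::-1])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Final model output
# ---------------------------------------------------------------------------

def model_status(model: GeneModel, n_7tm6: int | None = None) -> str:
    parts = [
        model.completeness,
        "start" if model.has_start else "no-start",
        "stop" if model.has_stop else "no-stop",
        "pseudo:" + ",".join(sorted(model.pseudo_defects)) if model.pseudo_defects else "normal",
    ]
    if n_7tm6 is not None:
        parts.append(f"7tm_6={n_7tm6}")
    return "|".join(parts)


def models_to_transcripts(
    models: list[GeneModel], domain_counts: dict[str, int] | None = None
) -> list[TranscriptAnnotation]:
    out = []
    for m in models:
        n = domain_counts.get(m.name) if domain_counts else None
        out.append(
            TranscriptAnnotation(
                transcript_id=f"{m.name}.t1",
                gene_id=m.name,
                scaffold=m.scaffold,
                strand=m.strand,
                exons=sorted(m.exons),
                source=GFF_SOURCE,
                attributes={"status": model_status(m, n)},
            )
        )
    return out


def write_bed12(models: list[GeneModel], domain_counts: dict[str, int] | None = None) -> str:
    """BED12 plus a 13th status column; 0-based half-open coordinates."""
    lines = []
    for m in models:
        if not m.exons:
            raise ValueError(f"model {m.name} has no exons")
        exons = m.exons_genomic
        start, end = exons[0][0], exons[-1][1]
        sizes = ",".join(str(e - s) for s, e in exons) + ","
        starts = ",".join(str(s - start) for s, _ in exons) + ","
        n = domain_counts.get(m.name) if domain_counts else None
        lines.append(
            "\t".join(
                [
                    m.scaffold, str(start), str(end), m.name,
                    str(int(round(m.score))), m.strand, str(start), str(end),
                    "0", str(len(exons)), sizes, starts,
                    model_status(m, n),
                ]
            )
        )
    return "\n".join(lines) + "\n" if lines else ""


def write_outputs(
    models: list[GeneModel],
    genome: SequenceSet,
    domain_counts: dict[str, int] | None = None,
) -> dict[str, str]:
    """Render the final gene models as GFF3, BED12+1, CDS and protein FASTA."""
    for m in models:
        if not m.exons:
            raise ValueError(f"model {m.name} has no exons")
        for s, e in m.exons:
            if not (0 <= s < e <= len(genome[m.scaffold])):
                raise ValueError(f"model {m.name}: exon [{s},{e}) outside scaffold")
    gff3 = write_transcripts_gff3(models_to_transcripts(models, domain_counts))
    bed = write_bed12(models, domain_counts)
    cds_fa = write_fasta((m.name, m.cds) for m in models)
    prot_fa = write_fasta((m.name, m.protein) for m in models)
    return {"gff3": gff3, "bed": bed, "cds_fasta": cds_fa, "protein_fasta": prot_fa}
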