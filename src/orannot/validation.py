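"""External validator parsing and summary statistics.

Predicted OR proteins are validated with evidence the user computes with
third-party tools: an hmmsearch per-domain table against the Pfam 7tm_6
domain (the family domain of insect ORs), per-protein transmembrane-helix
(TMH) predictions from up to three methods, and motif-scan hits.  When all
three TMH methods are supplied a residue-level majority-vote consensus is
computed.  The summary collects the totals a curator needs: genes/fragments,
complete vs partial, START presence, pseudogene status, 7tm_6 counts and
novelty against a user-provided annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

from .core import GeneModel, TranscriptAnnotation, interval_overlap
from .io_formats import AnnotationWarning, _as_handle

MIN_CONSENSUS_HELIX = 9  # residues


@dataclass
class ValidationRecord:
    model_name: str
    n_7tm6_domains: int = 0
    tmh_counts: dict[str, int] = field(default_factory=dict)
    consensus_helices: list[tuple[int, int]] = field(default_factory=list)
    motif_hits: list[tuple[str, int, float]] = field(default_factory=list)


@dataclass
class SummaryReport:
    total: int
    complete: int
    partial: int
    with_start: int
    without_start: int
    pseudogenous: int
    with_7tm6: int
    with_multiple_7tm6: int
    novel_loci: Optional[int]
    tmh_histogram: dict[str, dict[int, int]]

    def __post_init__(self) -> None:
        assert self.complete + self.partial == self.total
        assert self.with_start + self.without_start == self.total


# ---------------------------------------------------------------------------
# hmmsearch per-domain table
# ---------------------------------------------------------------------------

def parse_domain_table(stream: Union[str, TextIO]) -> dict[str, int]:
    """Count 7tm_6 domain hits per protein from an hmmsearch --domtblout
    table.  Every reported row counts; the tool's own inclusion threshold is
    trusted as-is."""
    counts: dict[str, int] = {}
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 13:
            warnings.warn(f"domain table line {lineno} malformed; skipped", AnnotationWarning)
            continue
        counts[cols[0]] = counts.get(cols[0], 0) + 1
    return counts


# ---------------------------------------------------------------------------
# TMH prediction dialects
# ---------------------------------------------------------------------------

def parse_tmh(stream: Union[str, TextIO], method: str) -> dict[str, list[tuple[int, int]]]:
    """Per-protein helix intervals (1-based inclusive) from one predictor.

    ``method`` selects the dialect: ``tmhmm`` (long format ``TMhelix`` rows),
    ``hmmtop`` (``>HP:`` topology lines) or ``phobius`` (long format ``FT
    TRANSMEM`` rows).
    """
    handle = _as_handle(stream)
    helices: dict[str, list[tuple[int, int]]] = {}
    if method == "tmhmm":
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) >= 5 and cols[2] == "TMhelix":
                helices.setdefault(cols[0], []).append((int(cols[3]), int(cols[4])))
            elif cols and cols[0] not in helices:
                helices.setdefault(cols[0], [])
    elif method == "hmmtop":
        for raw in handle:
            line = raw.strip()
            if not line.startswith(">HP:"):
                continue
            cols = line.split()
            # >HP: <len> <name> <IN|OUT> <N> <pos1> ... <pos2N>
            name = cols[2]
            n = int(cols[4])
            pos = [int(x) for x in cols[5 : 5 + 2 * n]]
            helices[name] = [(pos[2 * i], pos[2 * i + 1]) for i in range(n)]
    elif method == "phobius":
        current = None
        for raw in handle:
            cols = raw.split()
            if not cols:
                continue
            if cols[0] == "ID":
                current = cols[1]
                helices.setdefault(current, [])
            elif cols[0] == "FT" and len(cols) >= 4 and cols[1] == "TRANSMEM":
                if current is None:
                    warnings.warn("TRANSMEM row before ID; skipped", AnnotationWarning)
                    continue
                helices[current].append((int(cols[2]), int(cols[3])))
    else:
        raise ValueError(f"unknown TMH dialect: {method}")
    return helices


def consensus_tmh(
    per_method: dict[str, list[tuple[int, int]]], protein_length: int
) -> list[tuple[int, int]]:
    """Majority-vote consensus helices from exactly three TMH methods.

    A residue is membrane if >= 2 of the 3 methods place it inside a helix;
    maximal membrane runs of at least 9 residues become consensus helices.
    """
    if len(per_method) != 3:
        raise ValueError("consensus requires exactly three methods")
    votes = [0] * (protein_length + 2)  # 1-based
    for intervals in per_method.values():
        for s, e in intervals:
            for i in range(max(1, s), min(protein_length, e) + 1):
                votes[i] += 1
    out: list[tuple[int, int]] = []
    run_start = None
    for i in range(1, protein_length + 2):
        member = i <= protein_length and votes[i] >= 2
        if member and run_start is None:
            run_start = i
        elif not member and run_start is not None:
            if i - run_start >= MIN_CONSENSUS_HELIX:
                out.append((run_start, i - 1))
            run_start = None
    return out


# ---------------------------------------------------------------------------
# Motif-scan hits (parse-and-report only)
# ---------------------------------------------------------------------------

def parse_motif_hits(stream: Union[str, TextIO]) -> dict[str, list[tuple[str, int, float]]]:
    """Tab-separated motif-scan rows: protein, motif id, position, score."""
    hits: dict[str, list[tuple[str, int, float]]] = {}
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            warnings.warn(f"motif line {lineno} malformed; skipped", AnnotationWarning)
            continue
        hits.setdefault(cols[0], []).append((cols[1], int(cols[2]), float(cols[3])))
    return hits


# ---------------------------------------------------------------------------
# Novel-locus counting and the summary
# ---------------------------------------------------------------------------

def count_novel_loci(
    models: list[GeneModel], user_transcripts: list[TranscriptAnnotation]
) -> tuple[int, list[GeneModel], list[TranscriptAnnotation]]:
    """Models whose exons share no base with any user-annotation exon on the
    same strand are novel.  Also returns the user transcripts overlapping
    any prediction (the trimmed annotation)."""
    novel: list[GeneModel] = []
    overlapping: list[TranscriptAnnotation] = []

    def overlaps(m: GeneModel, t: TranscriptAnnotation) -> bool:
        if t.scaffold != m.scaffold or t.strand != m.strand:
            return False
        return any(
            interval_overlap(x, y) > 0 for x in m.exons for y in t.exons
        )

    for m in models:
        if not any(overlaps(m, t) for t in user_transcripts):
            novel.append(m)
    for t in user_transcripts:
        if any(overlaps(m, t) for m in models):
            overlapping.append(t)
    return len(novel), novel, overlapping


def summarize(
    models: list[GeneModel],
    domain_counts: Optional[dict[str, int]] = None,
    tmh: Optional[dict[str, dict[str, list[tuple[int, int]]]]] = None,
    user_transcripts: Optional[list[TranscriptAnnotation]] = None,
) -> SummaryReport:
    """Assemble the output summary; internal sums are asserted to reconcile.

    ``tmh`` maps method -> protein -> helix intervals.
    """
    complete = sum(1 for m in models if m.completeness == "complete")
    with_start = sum(1 for m in models if m.has_start)
    pseudo = sum(1 for m in models if m.is_pseudo)
    d = domain_counts or {}
    with_7tm6 = sum(1 for m in models if d.get(m.name, 0) >= 1)
    multi_7tm6 = sum(1 for m in models if d.get(m.name, 0) >= 2)
    novel = None
    if user_transcripts is not None:
        novel, _, _ = count_novel_loci(models, user_transcripts)
    histogram: dict[str, dict[int, int]] = {}
    for method, per_protein in (tmh or {}).items():
        hist: dict[int, int] = {}
        for m in models:
            n = len(per_protein.get(m.name, []))
            hist[n] = hist.get(n, 0) + 1
        histogram[method] = hist
    return SummaryReport(
        total=len(models),
        complete=complete,
        partial=len(models) - complete,
        with_start=with_start,
        without_start=len(models) - with_start,
        pseudogenous=pseudo,
        with_7tm6=with_7tm6,
        with_multiple_7tm6=multi_7tm6,
        novel_loci=novel,
        tmh_histogram=histogram,
    )
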