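"""Core domain types shared across the annotation pipeline.

Coordinate conventions
----------------------
All nucleotide intervals are 0-based half-open on the forward strand of the
scaffold, everywhere inside the package.  Conversion to 1-based inclusive
happens only when writing/reading GFF; BED stays 0-based half-open.  Protein
(query) coordinates are 1-based inclusive amino-acid positions, the usual
protein convention.

For minus-strand features the interval endpoints still refer to the forward
strand (start < end); *list order* of exon segments reflects transcription
order, so a minus-strand exon chain runs from high to low forward
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


def aa_to_nt(n_aa: int) -> int:
    """Nucleotide length encoding ``n_aa`` amino acids (no split codons)."""
    return 3 * n_aa


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def aa_span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in residues of two 1-based inclusive amino-acid spans."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


@dataclass
class ExonSegment:
    """One aligned exon of a spliced protein-to-genome alignment.

    ``target`` is the forward-strand nt interval; ``query`` the 1-based
    inclusive aa span it encodes.  ``phase`` is the offset of the first
    nucleotide within its codon (0 for codon-aligned exons).  ``frameshift``
    marks exons whose target arithmetic is not a whole number of codons
    (indels relative to the query reading frame).
    """

    target: tuple[int, int]
    query: tuple[int, int]
    phase: int = 0
    frameshift: bool = False

    @property
    def target_len(self) -> int:
        return self.target[1] - self.target[0]

    @property
    def query_len(self) -> int:
        return self.query[1] - self.query[0] + 1


@dataclass
class AlignmentHit:
    """One spliced protein-to-genome alignment (a gene record in the input).

    Segments are stored in transcription order.
    """

    hit_id: str
    query_id: str
    query_span: tuple[int, int]
    target_id: str
    target_span: tuple[int, int]
    strand: str
    score: float
    segments: list[ExonSegment]
    defects: set[str] = field(default_factory=set)

    @property
    def segments_genomic(self) -> list[ExonSegment]:
        """Segments sorted by ascending forward-strand coordinate."""
        return sorted(self.segments, key=lambda s: s.target[0])

    def validate(self) -> None:
        if not self.segments:
            raise ValueError(f"hit {self.hit_id}: no segments")
        gen = self.segments_genomic
        for a, b in zip(gen, gen[1:]):
            if a.target[1] > b.target[0]:
                raise ValueError(f"hit {self.hit_id}: overlapping segments")


@dataclass
class TranscriptAnnotation:
    """A transcript from a GFF annotation: its exon chain on a scaffold."""

    transcript_id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class SequenceSet:
    """An id -> residue-string map with a declared alphabet."""

    sequences: dict[str, str]
    alphabet: str  # "nucleotide" | "protein"

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


@dataclass
class Locus:
    """A maximal positive run of alignment coverage: a rough gene locus."""

    scaffold_id: str
    interval: tuple[int, int]
    supporting_hit_ids: list[str]
    best_hit_id: Optional[str] = None
    best_query_id: Optional[str] = None


@dataclass
class JunctionInfo:
    """Bookkeeping for one stitched fragment junction."""

    overlap_aa: int
    window_nt: int
    donor_offset: Optional[int]  # nt kept from the upstream fragment
    intron: Optional[tuple[int, int]]  # forward-strand interval
    n_candidates: int = 0


@dataclass
class StitchedModel:
    """A preliminary (P1) gene model: stitched exon chain of the best query."""

    query_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # transcription order, forward coords
    source_hit_ids: list[str]
    score: float
    defects: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)
    junctions: list[JunctionInfo] = field(default_factory=list)
    query_span: Optional[tuple[int, int]] = None

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        gen = self.exons_genomic
        return (gen[0][0], gen[-1][1])


@dataclass
class GeneModel:
    """A finalized gene model with CDS, protein and status flags."""

    name: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # transcription order, forward coords
    has_start: bool
    has_stop: bool
    pseudo_defects: set[str]
    completeness: str  # "complete" | "partial"
    provenance: str  # "P1" | "P2" | "merged"
    best_query_id: str
    protein: str
    cds: str
    score: float = 0.0
    junctions: list[JunctionInfo] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    query_span: Optional[tuple[int, int]] = None

    @property
    def exons_genomic(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        gen = self.exons_genomic
        return (gen[0][0], gen[-1][1])

    @property
    def is_pseudo(self) -> bool:
        return bool(self.pseudo_defects)

    @property
    def protein_len(self) -> int:
        """Protein length excluding a terminal stop."""
        p = self.protein
        if p.endswith("*"):
            p = p[:-1]
        return len(p)


@dataclass
class AnnotatorConfig:
    """Tunable parameters of the annotation pipeline.

    min_complete_len
        minimum protein length (aa) to call a model complete; default 300.
    max_extension
        cap, in nt, on per-side locus extension before refinement; default
        6000 (empirical insect intergenic distance).
    terminal_search_window
        how far (in codons) to scan for START/STOP beyond the alignment ends.
    isoform_overlap_frac
        query-region overlap below which two overlapping models are kept as
        putative isoforms; default 0.20.
    eval_tolerance_e
        terminal-exon free-end tolerance (nt) used by the evaluator.
    min_intron
        minimum intron length (nt) a stitched junction may create.
    """

    min_complete_len: int = 300
    max_extension: int = 6000
    terminal_search_window: int = 20
    isoform_overlap_frac: float = 0.20
    eval_tolerance_e: int = 10
    min_intron: int = 30

    def __post_init__(self) -> None:
        if self.min_complete_len <= 0 or self.max_extension <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 < self.isoform_overlap_frac < 1.0):
            raise ValueError("isoform_overlap_frac must be in (0,1)")
        if self.eval_tolerance_e < 0 or self.min_intron <= 0:
            raise ValueError("invalid tolerance/min_intron")
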