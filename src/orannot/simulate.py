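"""Synthetic genomes, ground truth, and alignment files for the pipeline.

The generator implants tandem arrays of multi-exon genes (4-9 exons by
default, the exon-count range of Hymenopteran OR subfamilies) into random
background scaffolds.  Each gene is an ATG-initiated, stop-terminated CDS
split by gt…ag introns, optionally pseudogenized (one in-frame stop or a
1-nt frameshift).  Matching alignment files in the Exonerate-with-GFF
dialect are emitted with the pathologies the pipeline must repair:

* redundant queries per locus (decoys: mutated copies of the true protein,
  always scoring below the self alignment);
* fragmented alignments split at one intron, the two fragments' query spans
  overlapping by k aa because each boundary was wrongly extended ~3k/2 nt
  into the intron.

For fragmented junctions the intron's splice-scan windows are filled with C
runs so the true gt/ag pair is the *unique* valid candidate in the overlap
window, making exact-recovery checks well-posed.  Identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .core import SequenceSet, TranscriptAnnotation, revcomp
from .io_formats import translate_cds, write_fasta, write_transcripts_gff3

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {}  # aa -> list of codons, built once
for _c in [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]:
    _aa = translate_cds(_c)
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)
STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for the generated fixtures.

    Intron lengths respect the stringent cap (<= 2000 nt) recommended when
    producing the alignments, which is what keeps tandem copies separable.
    """

    seed: int = 0
    n_scaffolds: int = 5
    genes_per_scaffold: int = 4
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_len_aa: tuple[int, int] = (25, 60)
    intron_len: tuple[int, int] = (40, 1500)
    intergenic_gap: tuple[int, int] = (300, 1000)
    pseudogene_fraction: float = 0.0
    fragment_overlap_k: tuple[int, int] = (3, 8)
    fraction_fragmented: float = 0.0
    n_decoy_queries: int = 1
    decoy_sub_rate: float = 0.10
    minus_strand_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.intron_len[1] > 2000:
            raise ValueError("intron cap is 2000 nt")
        if self.intron_len[0] < 3 * self.fragment_overlap_k[1] + 8:
            raise ValueError("introns too short for unique-splice construction")
        for frac in (self.pseudogene_fraction, self.fraction_fragmented,
                     self.decoy_sub_rate, self.minus_strand_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0,1]")
        if self.exon_len_aa[0] < self.fragment_overlap_k[1] + 2:
            raise ValueError("exons too short for fragment overlaps")


@dataclass
class AlignmentRecord:
    """One alignment as planned by the generator (the ledger entry)."""

    query_id: str
    target_id: str
    strand: str
    score: int
    # transcription order; query intervals 1-based inclusive aa
    segments: list[tuple[tuple[int, int], tuple[int, int]]]
    gene_id: str
    # optional per-exon Align triples overriding the default one-per-exon
    # (used for frameshift exons): list parallel to segments, each a list of
    # (coding_offset_nt_within_exon, query_start_aa, nt_len)
    triples: list[list[tuple[int, int, int]] | None] = field(default_factory=list)


@dataclass
class FragmentationRecord:
    gene_id: str
    intron_index: int
    overlap_k: int
    intron: tuple[int, int]  # forward-strand coordinates of the true intron


@dataclass
class TruthLedger:
    genome: SequenceSet
    transcripts: list[TranscriptAnnotation]
    proteins: dict[str, str]  # gene_id -> clean protein (the self query)
    defects: dict[str, set[str]]  # gene_id -> pseudogene defect labels
    fragmentation: dict[str, FragmentationRecord]
    alignments: list[AlignmentRecord]
    queries: SequenceSet = None  # type: ignore[assignment]


def _random_protein(rng: random.Random, n: int) -> str:
    return "M" + "".join(rng.choice(AA20) for _ in range(n - 1))


def _cds_for(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def generate_genome(config: SimulationConfig) -> TruthLedger:
    """Build scaffolds with implanted genes and plan matching alignments."""
    rng = random.Random(config.seed)
    genomes: dict[str, str] = {}
    transcripts: list[TranscriptAnnotation] = []
    proteins: dict[str, str] = {}
    defects: dict[str, set[str]] = {}
    fragmentation: dict[str, FragmentationRecord] = {}
    records: list[AlignmentRecord] = []
    queries: dict[str, str] = {}

    for si in range(config.n_scaffolds):
        scaffold = f"scaf{si + 1}"
        parts: list[str] = []
        cursor = 0

        def emit_background(n: int) -> None:
            nonlocal cursor
            parts.append("".join(rng.choice("ACGT") for _ in range(n)))
            cursor += n

        emit_background(rng.randint(*config.intergenic_gap))
        for gi in range(config.genes_per_scaffold):
            gene_id = f"s{si + 1}g{gi + 1}"
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            fragmented = rng.random() < config.fraction_fragmented
            pseudo = rng.random() < config.pseudogene_fraction
            gene = _build_gene(rng, config, gene_id, fragmented, pseudo)

            g0 = cursor
            seq = gene["seq"] if strand == "+" else revcomp(gene["seq"])
            parts.append(seq)
            cursor += len(seq)
            glen = len(seq)

            def fwd(iv: tuple[int, int]) -> tuple[int, int]:
                if strand == "+":
                    return (g0 + iv[0], g0 + iv[1])
                return (g0 + glen - iv[1], g0 + glen - iv[0])

            transcripts.append(
                TranscriptAnnotation(
                    transcript_id=f"{gene_id}.t1",
                    gene_id=gene_id,
                    scaffold=scaffold,
                    strand=strand,
                    exons=sorted(fwd(iv) for iv in gene["exons"]),
                    source="truth",
                )
            )
            proteins[gene_id] = gene["protein"]
            defects[gene_id] = gene["defects"]
            queries[gene_id] = gene["protein"]
            if gene["frag"] is not None:
                fragmentation[gene_id] = FragmentationRecord(
                    gene_id=gene_id,
                    intron_index=gene["frag"]["intron_index"],
                    overlap_k=gene["frag"]["k"],
                    intron=fwd(gene["frag"]["intron"]),
                )
            for rec in gene["alignments"]:
                records.append(
                    AlignmentRecord(
                        query_id=rec["query"].replace("SELF", gene_id),
                        target_id=scaffold,
                        strand=strand,
                        score=rec["score"],
                        segments=[(fwd(t), q) for t, q in rec["segments"]],
                        gene_id=gene_id,
                        triples=rec["triples"],
                    )
                )
                if rec["query"].startswith("SELF_d"):
                    queries[rec["query"].replace("SELF", gene_id)] = rec["protein"]
            emit_background(rng.randint(*config.intergenic_gap))
        genomes[scaffold] = "".join(parts)

    ledger = TruthLedger(
        genome=SequenceSet(genomes, "nucleotide"),
        transcripts=transcripts,
        proteins=proteins,
        defects=defects,
        fragmentation=fragmentation,
        alignments=records,
        queries=SequenceSet(queries, "protein"),
    )
    return ledger


def _build_gene(
    rng: random.Random,
    config: SimulationConfig,
    gene_id: str,
    fragmented: bool,
    pseudo: bool,
) -> dict:
    """One gene in local coding coordinates (0 = first CDS base)."""
    n_ex = rng.randint(*config.exons_per_gene)
    aa_lens = [rng.randint(*config.exon_len_aa) for _ in range(n_ex)]
    total_aa = sum(aa_lens)
    protein = _random_protein(rng, total_aa)
    cds = _cds_for(rng, protein)
    stop = rng.choice(STOPS)

    frag_intron = rng.randint(0, n_ex - 2) if (fragmented and n_ex >= 2) else None
    k = rng.randint(*config.fragment_overlap_k) if frag_intron is not None else 0
    u, m = k // 2, k - k // 2  # wrong residues carried up/downstream

    # introns; the fragmented junction gets C-filled splice-scan windows so
    # the true gt/ag pair is the unique valid stitch candidate
    introns: list[str] = []
    for j in range(n_ex - 1):
        ilen = rng.randint(*config.intron_len)
        interior = "".join(rng.choice("ACGT") for _ in range(ilen - 4))
        body = "gt" + interior + "ag"
        if j == frag_intron:
            body = (
                "gt" + "C" * (3 * u + 2)
                + interior[3 * u + 2 : ilen - 4 - (3 * m + 2)]
                + "C" * (3 * m + 2) + "ag"
            )
            assert len(body) == ilen
        introns.append(body.upper())

    # pseudogenizing mutation
    gene_defects: set[str] = set()
    fs_exon = fs_res = None
    if pseudo:
        kind = rng.choice(["inframe_stop", "frameshift"])
        bounds = []
        acc = 0
        for a in aa_lens:
            bounds.append((acc + 1, acc + a))  # 1-based residue span per exon
            acc += a
        if kind == "inframe_stop":
            res = rng.randint(max(2, total_aa // 4), max(2, 3 * total_aa // 4))
            cds = cds[: 3 * (res - 1)] + rng.choice(STOPS) + cds[3 * res :]
            gene_defects.add("inframe_stop")
        else:
            # delete 1 nt inside an internal codon of an internal exon
            x = rng.randint(1, n_ex - 2) if n_ex >= 3 else 0
            r1, r2 = bounds[x]
            fs_res = rng.randint(r1 + 1, r2 - 1)
            fs_exon = x
            cds = cds[: 3 * (fs_res - 1) + 2] + cds[3 * fs_res :]
            gene_defects.add("frameshift")

    # assemble coding-local sequence and exon intervals
    exon_ivs: list[tuple[int, int]] = []
    pieces: list[str] = []
    pos = 0
    cds_cursor = 0
    res_cursor = 0
    for i, a in enumerate(aa_lens):
        nt = 3 * a
        if fs_exon == i:
            nt -= 1
        piece = cds[cds_cursor : cds_cursor + nt]
        if i == n_ex - 1:
            piece += stop
        exon_ivs.append((pos, pos + len(piece)))
        pieces.append(piece)
        pos += len(piece)
        cds_cursor += nt
        res_cursor += a
        if i < n_ex - 1:
            pieces.append(introns[i])
            pos += len(introns[i])
    seq = "".join(pieces)

    # --- plan alignments (local coding coordinates) -----------------------
    res_bounds = []
    acc = 0
    for a in aa_lens:
        res_bounds.append((acc + 1, acc + a))
        acc += a

    def seg(i: int, qs: int | None = None, qe: int | None = None,
            ext5: int = 0, ext3: int = 0) -> tuple[tuple[int, int], tuple[int, int]]:
        """Exon i as an alignment segment, optionally trimmed in query space
        and/or extended in nt at either end; the stop codon is never part of
        an alignment."""
        r1, r2 = res_bounds[i]
        s, e = exon_ivs[i]
        if i == n_ex - 1:
            e -= 3  # exclude stop codon
        qs = r1 if qs is None else qs
        qe = r2 if qe is None else qe
        s += 3 * (qs - r1)
        e -= 3 * (r2 - qe)  # exon_ivs already reflect any frameshift deletion
        return ((s - ext5, e + ext3), (qs, qe))

    def fs_triples(i: int) -> list[tuple[int, int, int]] | None:
        if fs_exon != i:
            return None
        r1, r2 = res_bounds[i]
        lc = fs_res - r1
        return [(0, r1, 3 * lc), (3 * lc + 2, fs_res + 1, 3 * (r2 - fs_res))]

    alignments: list[dict] = []
    self_score = 5 * total_aa
    if frag_intron is None:
        segs = [seg(i) for i in range(n_ex)]
        alignments.append(
            {"query": "SELF", "score": self_score, "segments": segs,
             "triples": [fs_triples(i) for i in range(n_ex)], "protein": protein}
        )
    else:
        j = frag_intron
        q = res_bounds[j][1]  # boundary residue
        # qe/qs beyond the exon's true residue span make seg() extend the
        # segment into the intron: the wrong-extension pathology
        seg_up = [seg(i) for i in range(j)] + [seg(j, qe=q + u)]
        seg_down = [seg(j + 1, qs=q - m + 1)] + [seg(i) for i in range(j + 2, n_ex)]
        alignments.append(
            {"query": "SELF", "score": 5 * (q + u), "segments": seg_up,
             "triples": [fs_triples(i) for i in range(j + 1)], "protein": protein}
        )
        alignments.append(
            {"query": "SELF", "score": 5 * (total_aa - q + m), "segments": seg_down,
             "triples": [fs_triples(i) for i in range(j + 1, n_ex)],
             "protein": protein}
        )

    for d in range(config.n_decoy_queries):
        prot = list(protein)
        n_sub = 0
        for i in range(1, len(prot)):
            if rng.random() < config.decoy_sub_rate:
                prot[i] = rng.choice(AA20.replace(prot[i], ""))
                n_sub += 1
        t1, t2 = rng.randint(1, 3), rng.randint(1, 3)
        penalty = 10 * n_sub + 5 * (t1 + t2) + 1
        dq = f"SELF_d{d + 1}"
        dprot = "".join(prot)
        if frag_intron is None:
            segs = [seg(i) for i in range(n_ex)]
            segs[0] = seg(0, qs=1 + t1)
            segs[-1] = seg(n_ex - 1, qe=total_aa - t2) if n_ex > 1 else seg(
                0, qs=1 + t1, qe=total_aa - t2
            )
            alignments.append(
                {"query": dq, "score": max(1, self_score - penalty),
                 "segments": segs, "triples": [fs_triples(i) for i in range(n_ex)],
                 "protein": dprot}
            )
        else:
            j = frag_intron
            q = res_bounds[j][1]
            seg_up = [seg(i) for i in range(j + 1)]
            seg_up[0] = seg(0, qs=1 + t1) if j > 0 else seg(0, qs=1 + t1, qe=q)
            seg_down = [seg(i) for i in range(j + 1, n_ex)]
            seg_down[-1] = (
                seg(n_ex - 1, qe=total_aa - t2)
                if j + 1 < n_ex - 1
                else seg(n_ex - 1, qs=q + 1, qe=total_aa - t2)
            )
            alignments.append(
                {"query": dq, "score": max(1, 5 * q - penalty), "segments": seg_up,
                 "triples": [fs_triples(i) for i in range(j + 1)], "protein": dprot}
            )
            alignments.append(
                {"query": dq, "score": max(1, 5 * (total_aa - q) - penalty),
                 "segments": seg_down,
                 "triples": [fs_triples(i) for i in range(j + 1, n_ex)],
                 "protein": dprot}
            )

    frag = None
    if frag_intron is not None:
        frag = {
            "intron_index": frag_intron,
            "k": k,
            "intron": (exon_ivs[frag_intron][1], exon_ivs[frag_intron + 1][0]),
        }
    return {
        "seq": seq,
        "exons": exon_ivs,
        "protein": protein,
        "defects": gene_defects,
        "frag": frag,
        "alignments": alignments,
    }


def make_fragment_pair(
    seed: int = 0,
    total_aa: int = 150,
    frag1_span: tuple[int, int] = (5, 50),
    frag2_span: tuple[int, int] = (45, 150),
    intron_len: int = 300,
    scaffold: str = "scaf1",
):
    """The textbook wrong-extension case: one two-exon gene whose alignment
    was split at the intron into fragments with overlapping query spans.

    Returns ``(genome, protein, [fragment1, fragment2], true_intron)`` where
    the fragments are :class:`AlignmentHit` objects whose boundaries extend
    wrongly into the intron, and ``true_intron`` is the implanted gt…ag
    intron interval.  The intron's splice-scan windows are C-filled so the
    true splice pair is the unique valid stitch candidate.
    """
    from .core import AlignmentHit, ExonSegment

    rng = random.Random(seed)
    a1, b1 = frag1_span
    a2, b2 = frag2_span
    k = b1 - a2 + 1
    if not (0 <= k < b1 - a1 and b2 == total_aa):
        raise ValueError("fragment spans must overlap and cover the protein end")
    q = (b1 + a2) // 2  # true exon boundary residue
    u, m = b1 - q, q - a2 + 1

    protein = _random_protein(rng, total_aa)
    cds = _cds_for(rng, protein)
    interior = "".join(rng.choice("ACGT") for _ in range(intron_len - 4))
    intron = (
        "gt" + "C" * (3 * u + 2)
        + interior[3 * u + 2 : intron_len - 4 - (3 * m + 2)]
        + "C" * (3 * m + 2) + "ag"
    ).upper()
    lead = rng.randint(50, 120)
    prefix = "".join(rng.choice("ACGT") for _ in range(lead))
    suffix = "".join(rng.choice("ACGT") for _ in range(100))
    exon1 = cds[: 3 * q]
    exon2 = cds[3 * q :] + rng.choice(STOPS)
    seq = prefix + exon1 + intron + exon2 + suffix

    e1 = (lead, lead + len(exon1))
    e2 = (e1[1] + intron_len, e1[1] + intron_len + len(exon2))
    frag1 = AlignmentHit(
        hit_id="frag1", query_id="query1", query_span=(a1, b1),
        target_id=scaffold, target_span=(e1[0] + 3 * (a1 - 1), e1[1] + 3 * u),
        strand="+", score=5 * (b1 - a1 + 1),
        segments=[ExonSegment(
            target=(e1[0] + 3 * (a1 - 1), e1[1] + 3 * u), query=(a1, b1)
        )],
    )
    frag2 = AlignmentHit(
        hit_id="frag2", query_id="query1", query_span=(a2, b2),
        target_id=scaffold, target_span=(e2[0] - 3 * m, e2[1] - 3),
        strand="+", score=5 * (b2 - a2 + 1),
        segments=[ExonSegment(
            target=(e2[0] - 3 * m, e2[1] - 3), query=(a2, b2)
        )],
    )
    genome = SequenceSet({scaffold: seq}, "nucleotide")
    return genome, protein, [frag1, frag2], (e1[1], e2[0])


# ---------------------------------------------------------------------------
# Exonerate-dialect emission
# ---------------------------------------------------------------------------

def emit_alignments(ledger: TruthLedger, config: SimulationConfig) -> str:
    """Render the planned alignments as Exonerate-with-GFF text."""
    out: list[str] = [
        "Command line: [exonerate --model protein2genome --showtargetgff yes]",
        "Hostname: [synthetic]",
        "",
    ]
    for idx, rec in enumerate(ledger.alignments, start=1):
        span = (
            min(t[0] for t, _ in rec.segments),
            max(t[1] for t, _ in rec.segments),
        )
        src = "exonerate:protein2genome:local"
        out.append("# --- START OF GFF DUMP ---")
        out.append("##gff-version 2")
        out.append(f"##source-version {src} 2.4.0")
        out.append(
            "\t".join(
                [rec.target_id, src, "gene", str(span[0] + 1), str(span[1]),
                 str(rec.score), rec.strand, ".",
                 f"gene_id {idx} ; sequence {rec.query_id} ; gene_orientation ."]
            )
        )
        aligns: list[str] = []
        triples_spec = rec.triples or [None] * len(rec.segments)
        for (t_iv, q_iv), triple in zip(rec.segments, triples_spec):
            out.append(
                "\t".join(
                    [rec.target_id, src, "exon", str(t_iv[0] + 1), str(t_iv[1]),
                     ".", rec.strand, ".", "insertions 0 ; deletions 0"]
                )
            )
            if triple is None:
                sub = [(0, q_iv[0], t_iv[1] - t_iv[0])]
            else:
                sub = triple
            for off, qs, n in sub:
                if rec.strand == "+":
                    t1 = t_iv[0] + off + 1
                else:
                    t1 = t_iv[1] - off  # first transcribed base, 1-based forward
                aligns.append(f"Align {t1} {qs} {n}")
        out.append(
            "\t".join(
                [rec.target_id, src, "similarity", str(span[0] + 1), str(span[1]),
                 str(rec.score), rec.strand, ".",
                 f"alignment_id {idx} ; Query {rec.query_id} ; " + " ; ".join(aligns)]
            )
        )
        out.append("# --- END OF GFF DUMP ---")
    out.append("-- completed exonerate analysis")
    return "\n".join(out) + "\n"


def write_bundle(ledger: TruthLedger, config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, truth GFF3, query FASTA and alignment text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "queries": outdir / "queries.fa",
        "truth_gff": outdir / "truth.gff3",
        "alignments": outdir / "alignments.exonerate.txt",
    }
    paths["genome"].write_text(write_fasta(ledger.genome.items()))
    paths["queries"].write_text(write_fasta(ledger.queries.items()))
    paths["truth_gff"].write_text(write_transcripts_gff3(ledger.transcripts))
    paths["alignments"].write_text(emit_alignments(ledger, config))
    return paths
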