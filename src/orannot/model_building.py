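"""From alignment islands to stitched gene models.

The pipeline keeps, per coverage island, only the best-scoring alignment and
hence one best query protein; all alignments of that query on the same
scaffold are then treated as fragments of one gene and stitched back
together.  Fragmentation arises when stringent intron caps split a gene's
alignment at a long intron; each fragment boundary is typically *extended*
wrongly into the intron, so the two fragments share a short overlapping query
region.  Stitching enumerates every way to split that overlap between the
two exons, keeps only splits flanked by a canonical gt…ag intron on the
coding strand, and picks the split whose translation is most similar to the
query residues it should encode.
"""

from __future__ import annotations

from typing import Literal, Union

from Bio.Align import substitution_matrices

from .core import (
    AlignmentHit,
    AnnotatorConfig,
    GeneModel,
    JunctionInfo,
    Locus,
    StitchedModel,
    aa_span_overlap,
    interval_overlap,
    revcomp,
)
from .io_formats import translate_cds

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def similarity_score(a: str, b: str) -> float:
    """Sum of BLOSUM62 similarities between two equal-length peptide strings."""
    total = 0.0
    for x, y in zip(a, b):
        try:
            total += _BLOSUM62[x, y]
        except (KeyError, IndexError):
            total += -4.0
    return total


def select_best_per_island(
    locus: Locus, hits_by_id: dict[str, AlignmentHit]
) -> tuple[AlignmentHit, str]:
    """Best supporting alignment by score; ties broken by query id then
    leftmost target start, for determinism."""
    candidates = [hits_by_id[h] for h in locus.supporting_hit_ids]
    if not candidates:
        raise ValueError(f"locus {locus.scaffold_id}:{locus.interval} has no hits")
    best = min(candidates, key=lambda h: (-h.score, h.query_id, h.target_span[0]))
    locus.best_hit_id = best.hit_id
    locus.best_query_id = best.query_id
    return best, best.query_id


def collect_best_query_hits(
    best_query: str, scaffold: str, hits: list[AlignmentHit]
) -> list[AlignmentHit]:
    """All alignments of the best query on the scaffold, in genomic order."""
    return sorted(
        (h for h in hits if h.query_id == best_query and h.target_id == scaffold),
        key=lambda h: h.target_span[0],
    )


def _follows(a: AlignmentHit, b: AlignmentHit) -> bool:
    """True if b transcriptionally follows a with advancing query coords."""
    if a.strand == "+":
        target_ok = b.target_span[0] >= a.target_span[1]
    else:
        target_ok = b.target_span[1] <= a.target_span[0]
    query_ok = (
        b.query_span[0] > a.query_span[0] and b.query_span[1] > a.query_span[1]
    )
    return target_ok and query_ok


def congruent(frag_a: AlignmentHit, frag_b: AlignmentHit) -> bool:
    """Can the two same-query fragments belong to one gene model?

    Requires identical strand, target order matching query order for that
    strand, and non-nested query spans.
    """
    if frag_a.strand != frag_b.strand or frag_a.target_id != frag_b.target_id:
        return False
    return _follows(frag_a, frag_b) or _follows(frag_b, frag_a)


def chain_fragments(fragments: list[AlignmentHit]) -> list[list[AlignmentHit]]:
    """Partition genomically sorted fragments into congruent runs
    (transcription order within each run)."""
    if not fragments:
        return []
    strand = fragments[0].strand
    ordered = sorted(
        fragments, key=lambda h: h.target_span[0], reverse=(strand == "-")
    )
    chains: list[list[AlignmentHit]] = [[ordered[0]]]
    for frag in ordered[1:]:
        if frag.strand == strand and _follows(chains[-1][-1], frag):
            chains[-1].append(frag)
        else:
            chains.append([frag])
    return chains


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def _to_rc(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - iv[1], length - iv[0])


def stitch(
    fragments: list[AlignmentHit],
    genome_seq: str,
    query_protein: str,
    config: AnnotatorConfig,
) -> list[StitchedModel]:
    """Stitch congruent same-query fragments into gene models.

    For each adjacent pair overlapping by k aa, all 3k+1 donor offsets are
    enumerated over the 3k-nt overlap window; only gt…ag-flanked candidates
    survive, and the one translating closest to the query (BLOSUM62 sum)
    wins, ties to the leftmost donor.  A junction with no valid candidate
    splits the model in two, each flagged ``unstitched_junction``.
    """
    if not fragments:
        return []
    strand = fragments[0].strand
    scaffold_len = len(genome_seq)
    # work on the coding strand: reverse-complement mapping for minus hits
    seq = genome_seq if strand == "+" else revcomp(genome_seq)

    def coding_exons(frag: AlignmentHit) -> list[list]:
        # [start, end, qstart, qend] in coding-strand coordinates,
        # transcription order == ascending
        if strand == "+":
            return [[s.target[0], s.target[1], s.query[0], s.query[1]] for s in frag.segments]
        return [[*_to_rc(s.target, scaffold_len), s.query[0], s.query[1]] for s in frag.segments]

    models: list[StitchedModel] = []
    chain: list[list] = []
    chain_state: dict = {}

    def open_chain(frag: AlignmentHit) -> None:
        chain_state.update(
            qstart=frag.query_span[0],
            qend=frag.query_span[1],
            hit_ids=[frag.hit_id],
            score=frag.score,
            defects=set(frag.defects),
            flags=set(),
            junctions=[],
        )
        chain.clear()
        chain.extend(coding_exons(frag))

    def close_chain() -> None:
        exons_coding = [(e[0], e[1]) for e in chain]
        if strand == "+":
            exons = exons_coding
        else:
            exons = [_to_rc(iv, scaffold_len) for iv in exons_coding]
        junctions = chain_state["junctions"]
        if strand == "-":
            junctions = [
                JunctionInfo(
                    j.overlap_aa, j.window_nt, j.donor_offset,
                    _to_rc(j.intron, scaffold_len) if j.intron else None,
                    j.n_candidates,
                )
                for j in junctions
            ]
        models.append(
            StitchedModel(
                query_id=fragments[0].query_id,
                scaffold=fragments[0].target_id,
                strand=strand,
                exons=exons,
                source_hit_ids=list(chain_state["hit_ids"]),
                score=chain_state["score"],
                defects=set(chain_state["defects"]),
                flags=set(chain_state["flags"]),
                junctions=junctions,
                query_span=(chain_state["qstart"], chain_state["qend"]),
            )
        )

    open_chain(fragments[0])
    for frag in fragments[1:]:
        exons = coding_exons(frag)
        k = chain_state["qend"] - frag.query_span[0] + 1
        joined = False
        if k <= 0:
            # junction already intronic: concatenate directly
            intron = (chain[-1][1], exons[0][0])
            if intron[1] - intron[0] < config.min_intron:
                chain_state["flags"].add("short_intron")
            chain_state["junctions"].append(
                JunctionInfo(0, 0, None, intron, n_candidates=0)
            )
            chain.extend(exons)
            joined = True
        else:
            window = 3 * k
            up_start, up_end = chain[-1][0], chain[-1][1]
            ds_start, ds_end = exons[0][0], exons[0][1]
            if up_end - up_start >= window and ds_end - ds_start >= window:
                target_res = query_protein[frag.query_span[0] - 1 : frag.query_span[0] - 1 + k]
                best = None  # (score, d, u_cut, a_cut)
                n_cand = 0
                for d in range(window + 1):
                    u_cut = up_end - window + d
                    a_cut = ds_start + d
                    if u_cut <= up_start or a_cut >= ds_end:
                        continue  # would empty an exon
                    if seq[u_cut : u_cut + 2].lower() != "gt":
                        continue
                    if seq[a_cut - 2 : a_cut].lower() != "ag":
                        continue
                    if a_cut - u_cut < config.min_intron:
                        continue
                    n_cand += 1
                    stitched = seq[up_end - window : u_cut] + seq[a_cut : ds_start + window]
                    cand_score = similarity_score(translate_cds(stitched), target_res)
                    if best is None or cand_score > best[0]:
                        best = (cand_score, d, u_cut, a_cut)
                if best is not None:
                    _, d, u_cut, a_cut = best
                    chain[-1][1] = u_cut
                    exons[0][0] = a_cut
                    chain_state["junctions"].append(
                        JunctionInfo(k, window, d, (u_cut, a_cut), n_cand)
                    )
                    chain.extend(exons)
                    joined = True
        if joined:
            chain_state["qend"] = max(chain_state["qend"], frag.query_span[1])
            chain_state["hit_ids"].append(frag.hit_id)
            chain_state["score"] += frag.score
            chain_state["defects"] |= frag.defects
        else:
            # no gt…ag-valid stitch: report fragments as separate models
            chain_state["flags"].add("unstitched_junction")
            close_chain()
            open_chain(frag)
            chain_state["flags"].add("unstitched_junction")
    close_chain()
    return models


# ---------------------------------------------------------------------------
# Overlap resolution (isoform rule)
# ---------------------------------------------------------------------------

def _ranking_key(model: GeneModel) -> tuple:
    return (
        model.completeness == "complete",
        model.protein_len,
        not model.is_pseudo,
        model.has_start,
    )


def resolve_overlap(
    model_a: GeneModel, model_b: GeneModel, config: AnnotatorConfig
) -> Union[Literal["both"], GeneModel]:
    """Apply the putative-isoform rule to two models on one scaffold.

    If the overlapping region is below the isoform threshold (default 20 %)
    of *both* models' regions, both are kept as putative isoforms/duplicated
    exons; otherwise the better model wins (completeness, protein length,
    non-pseudogenous, START presence, in that order).
    """
    if (
        model_a.best_query_id == model_b.best_query_id
        and model_a.query_span is not None
        and model_b.query_span is not None
    ):
        ov = aa_span_overlap(model_a.query_span, model_b.query_span)
        la = model_a.query_span[1] - model_a.query_span[0] + 1
        lb = model_b.query_span[1] - model_b.query_span[0] + 1
    else:
        ov = sum(
            interval_overlap(x, y)
            for x in model_a.exons_genomic
            for y in model_b.exons_genomic
        )
        la = sum(e - s for s, e in model_a.exons)
        lb = sum(e - s for s, e in model_b.exons)
    if la == 0 or lb == 0:
        return "both"
    if ov / la < config.isoform_overlap_frac and ov / lb < config.isoform_overlap_frac:
        return "both"
    return model_a if _ranking_key(model_a) >= _ranking_key(model_b) else model_b
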