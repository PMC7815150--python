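"""End-to-end annotation: alignments + genome + queries -> gene models.

Stages: per-scaffold coverage tracks and islands; best alignment and best
query per island; collection and stitching of the best queries' fragments;
optional external refinement (P2) and P1/P2 merging; terminal-codon search,
defect flagging and classification; overlap (isoform) resolution; naming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .core import (
    AlignmentHit,
    AnnotatorConfig,
    GeneModel,
    Locus,
    SequenceSet,
    StitchedModel,
)
from .io_formats import AnnotationWarning
from .locus_detection import build_coverage, find_islands
from .model_building import (
    chain_fragments,
    collect_best_query_hits,
    resolve_overlap,
    select_best_per_island,
    stitch,
)
from .refinement import ExternalRefiner, extend_locus, finalize, merge_p1_p2, name_model


@dataclass
class AnnotationResult:
    models: list[GeneModel]
    loci: list[Locus]
    n_hits: int
    warnings: list[str] = field(default_factory=list)


def annotate(
    hits: list[AlignmentHit],
    genome: SequenceSet,
    queries: SequenceSet,
    config: Optional[AnnotatorConfig] = None,
    refiner: Optional[ExternalRefiner] = None,
) -> AnnotationResult:
    config = config or AnnotatorConfig()
    hits_by_id = {h.hit_id: h for h in hits}
    all_loci: list[Locus] = []
    finalized: list[GeneModel] = []
    log: list[str] = []

    for scaffold in genome.sequences:
        scaffold_hits = [h for h in hits if h.target_id == scaffold]
        if not scaffold_hits:
            continue
        track = build_coverage(scaffold, len(genome[scaffold]), scaffold_hits)
        islands = find_islands(track, scaffold_hits)
        all_loci.extend(islands)

        best_queries: list[str] = []
        for locus in islands:
            _, query = select_best_per_island(locus, hits_by_id)
            if query not in best_queries:
                best_queries.append(query)

        stitched: list[StitchedModel] = []
        for query in best_queries:
            fragments = collect_best_query_hits(query, scaffold, scaffold_hits)
            for chain in chain_fragments(fragments):
                if query not in queries:
                    log.append(f"query {query} absent from query FASTA; skipped")
                    continue
                stitched.extend(
                    stitch(chain, genome[scaffold], queries[query], config)
                )

        for model in stitched:
            if "unstitched_junction" in model.flags:
                log.append(
                    f"{scaffold}: no gt..ag stitch for {model.query_id}; "
                    "fragments kept separate"
                )
            p1 = finalize(model, genome, config, provenance="P1")
            p2 = None
            if refiner is not None:
                window = extend_locus(model.span, len(genome[scaffold]), config)
                refined = refiner.refine(
                    genome, scaffold, window, model.query_id, queries[model.query_id]
                )
                if refined is not None:
                    refined.query_span = model.query_span
                    p2 = finalize(refined, genome, config, provenance="P2")
            finalized.extend(merge_p1_p2(p1, p2))

    # isoform / duplicate resolution per scaffold
    finalized.sort(key=lambda m: (m.scaffold, m.span[0], m.span[1]))
    kept: list[GeneModel] = []
    for model in finalized:
        winner = True
        for other in list(kept):
            if other.scaffold != model.scaffold:
                continue
            same_query = other.best_query_id == model.best_query_id
            spans_overlap = (
                other.strand == model.strand
                and other.span[0] < model.span[1]
                and model.span[0] < other.span[1]
            )
            if not (same_query or spans_overlap):
                continue
            verdict = resolve_overlap(other, model, config)
            if verdict == "both":
                continue
            if verdict is other:
                winner = False
                break
            kept.remove(other)
        if winner:
            kept.append(model)

    serial_by_scaffold: dict[str, int] = {}
    for model in kept:
        serial = serial_by_scaffold.get(model.scaffold, 0) + 1
        serial_by_scaffold[model.scaffold] = serial
        model.name = name_model(model, serial)

    for msg in log:
        warnings.warn(msg, AnnotationWarning)
    return AnnotationResult(models=kept, loci=all_loci, n_hits=len(hits), warnings=log)
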