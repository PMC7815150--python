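"""Per-nucleotide alignment coverage ("virtual scaffolds") and locus islands.

Every scaffold with alignments gets a virtual copy initialised to zero; each
aligned exon segment increments the count at every base it covers.  Maximal
runs of positive count are the rough gene loci.  Because intron length is
capped stringently when the alignments are produced, tandem gene copies end
up as closely situated but distinct islands, which is what lets the pipeline
separate them.  Introns inside an alignment contribute nothing, so a chimeric
alignment spanning two neighbouring genes cannot fuse their islands.
"""

from __future__ import annotations

import numpy as np

from .core import AlignmentHit, Locus


class CoverageTrack:
    """Exon-segment coverage counts along one scaffold."""

    def __init__(self, scaffold_id: str, length: int):
        self.scaffold_id = scaffold_id
        self.counts = np.zeros(length, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.counts)


def build_coverage(
    scaffold_id: str, scaffold_length: int, hits: list[AlignmentHit]
) -> CoverageTrack:
    """Count, per base, how many alignment exon segments cover it."""
    track = CoverageTrack(scaffold_id, scaffold_length)
    diff = np.zeros(scaffold_length + 1, dtype=np.int64)
    for hit in hits:
        if hit.target_id != scaffold_id:
            continue
        for seg in hit.segments:
            s, e = seg.target
            if s < 0 or e > scaffold_length:
                raise ValueError(
                    f"hit {hit.hit_id}: segment [{s},{e}) outside scaffold "
                    f"{scaffold_id} of length {scaffold_length}"
                )
            diff[s] += 1
            diff[e] -= 1
    track.counts = np.cumsum(diff[:-1]).astype(np.int32)
    return track


def find_islands(track: CoverageTrack, hits: list[AlignmentHit]) -> list[Locus]:
    """Maximal runs of positive coverage, left to right, with supporting hits.

    A hit supports every island its span overlaps (its own exons necessarily
    created part of that island's coverage or lie within the run).
    """
    positive = track.counts > 0
    if not positive.any():
        return []
    padded = np.concatenate(([False], positive, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]

    loci: list[Locus] = []
    for s, e in zip(starts, ends):
        supporting = [
            h.hit_id
            for h in hits
            if h.target_id == track.scaffold_id
            and any(seg.target[0] < e and seg.target[1] > s for seg in h.segments)
        ]
        loci.append(
            Locus(
                scaffold_id=track.scaffold_id,
                interval=(int(s), int(e)),
                supporting_hit_ids=supporting,
            )
        )
    return loci
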