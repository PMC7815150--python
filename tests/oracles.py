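"""Independent brute-force reference computations for the test suite.

These deliberately use naive per-position / exhaustive-enumeration
strategies, independent of the package's interval arithmetic, so the two
routes can be compared on small inputs.
"""

from __future__ import annotations

from itertools import combinations

from orannot.core import TranscriptAnnotation


def coverage_by_recount(length: int, segments: list[tuple[int, int]]) -> list[int]:
    counts = [0] * length
    for s, e in segments:
        for i in range(s, e):
            counts[i] += 1
    return counts


def islands_by_scan(counts: list[int]) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, c in enumerate(counts + [0]):
        if c > 0 and start is None:
            start = i
        elif c <= 0 and start is not None:
            out.append((start, i))
            start = None
    return out


def consensus_by_vote(
    per_method: dict[str, list[tuple[int, int]]], length: int, min_len: int = 9
) -> list[tuple[int, int]]:
    membrane = []
    for i in range(1, length + 1):
        votes = sum(
            any(s <= i <= e for s, e in ivs) for ivs in per_method.values()
        )
        membrane.append(votes >= 2)
    out = []
    start = None
    for idx, m in enumerate(membrane + [False]):
        pos = idx + 1
        if m and start is None:
            start = pos
        elif not m and start is not None:
            if pos - start >= min_len:
                out.append((start, pos - 1))
            start = None
    return out


# ---------------------------------------------------------------------------
# evaluator oracle
# ---------------------------------------------------------------------------

def _base_sets(transcripts: list[TranscriptAnnotation]) -> set:
    bases = set()
    for t in transcripts:
        for s, e in t.exons:
            for i in range(s, e):
                bases.add((t.scaffold, t.strand, i))
    return bases


def _exon_set(transcripts):
    flags = {}
    for t in transcripts:
        for idx, (s, e) in enumerate(t.exons):
            key = (t.scaffold, t.strand, s, e)
            f = flags.setdefault(key, [False, False])
            f[0] |= idx == 0
            f[1] |= idx == len(t.exons) - 1
    return flags


def _exon_pair_ok(p, pf, r, rf, e):
    if p[0] != r[0] or p[1] != r[1]:
        return False
    s_ok = p[2] == r[2] or (pf[0] and rf[0] and abs(p[2] - r[2]) <= e)
    e_ok = p[3] == r[3] or (pf[1] and rf[1] and abs(p[3] - r[3]) <= e)
    return s_ok and e_ok


def _max_matching_exhaustive(pred, pf, ref, rf, e):
    """Maximum one-to-one exon matching by exhaustive subset search."""
    pairs = [
        (i, j)
        for i, p in enumerate(pred)
        for j, r in enumerate(ref)
        if _exon_pair_ok(p, pf[p], r, rf[r], e)
    ]
    best = 0
    for size in range(min(len(pred), len(ref)), 0, -1):
        if size <= best:
            break
        for combo in combinations(pairs, size):
            if len({i for i, _ in combo}) == size and len({j for _, j in combo}) == size:
                best = size
                break
        if best:
            break
    return best


def _tx_match(p: TranscriptAnnotation, r: TranscriptAnnotation, e: int) -> bool:
    if (p.scaffold, p.strand) != (r.scaffold, r.strand) or len(p.exons) != len(r.exons):
        return False
    for idx, ((ps, pe), (rs, re_)) in enumerate(zip(p.exons, r.exons)):
        first, last = idx == 0, idx == len(p.exons) - 1
        if (ps != rs) if not first else (abs(ps - rs) > e):
            return False
        if (pe != re_) if not last else (abs(pe - re_) > e):
            return False
    return True


def _loci(transcripts):
    """Flood-fill transcript clusters through shared exonic bases."""
    remaining = list(transcripts)
    loci = []
    while remaining:
        group = [remaining.pop()]
        changed = True
        while changed:
            changed = False
            gb = _base_sets(group)
            for t in list(remaining):
                if _base_sets([t]) & gb:
                    group.append(t)
                    remaining.remove(t)
                    changed = True
        loci.append(group)
    return loci


def evaluate_exhaustively(predicted, reference, e):
    """All evaluator quantities by brute force; returns a plain dict."""
    pb, rb = _base_sets(predicted), _base_sets(reference)
    base = dict(tp=len(pb & rb), fp=len(pb - rb), fn=len(rb - pb))

    pf, rf = _exon_set(predicted), _exon_set(reference)
    pred_ex, ref_ex = sorted(pf), sorted(rf)
    tp = _max_matching_exhaustive(pred_ex, pf, ref_ex, rf, e)
    exon = dict(tp=tp, fp=len(pred_ex) - tp, fn=len(ref_ex) - tp)

    def exon_bases(x):
        return {(x[0], x[1], i) for i in range(x[2], x[3])}

    missed_exons = sum(1 for r in ref_ex if not (exon_bases(r) & pb))
    novel_exons = sum(1 for p in pred_ex if not (exon_bases(p) & rb))

    ref_loci, pred_loci = _loci(reference), _loci(predicted)
    matched_ref = sum(
        1 for loc in ref_loci
        if any(_tx_match(p, r, e) for r in loc for p in predicted)
    )
    matched_pred = sum(
        1 for loc in pred_loci
        if any(_tx_match(p, r, e) for p in loc for r in reference)
    )
    missed_loci = sum(1 for loc in ref_loci if not (_base_sets(loc) & pb))
    novel_loci = sum(1 for loc in pred_loci if not (_base_sets(loc) & rb))
    return dict(
        base=base,
        exon=exon,
        locus=dict(
            tp=matched_ref,
            fp=len(pred_loci) - matched_pred,
            fn=len(ref_loci) - matched_ref,
            tp_pred=matched_pred,
        ),
        missed_exons=missed_exons,
        novel_exons=novel_exons,
        missed_loci=missed_loci,
        novel_loci=novel_loci,
        n_ref_ex=len(ref_ex),
        n_pred_ex=len(pred_ex),
        n_ref_loci=len(ref_loci),
        n_pred_loci=len(pred_loci),
        matching_loci=matched_ref,
    )


def random_annotation(rng, scaffold="s", max_tx=3, max_exons=3, span=400):
    """A small random annotation for oracle comparisons."""
    out = []
    for t in range(rng.randint(1, max_tx)):
        strand = rng.choice("+-")
        n = rng.randint(1, max_exons)
        pos = rng.randint(0, span // 3)
        exons = []
        for _ in range(n):
            length = rng.randint(5, 40)
            exons.append((pos, pos + length))
            pos += length + rng.randint(5, 40)
        out.append(
            TranscriptAnnotation(
                transcript_id=f"t{t}",
                gene_id=f"g{t}",
                scaffold=scaffold,
                strand=strand,
                exons=exons,
            )
        )
    return out
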