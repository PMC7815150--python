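"""Annotation comparison at base, exon and locus level.

Sensitivity = TP/(TP+FN) and Precision = TP/(TP+FP), computed at three
granularities against a reference annotation:

* base — exonic nucleotides, strand-aware;
* exon — unique exon intervals matched one-to-one; internal boundaries must
  be exact, transcript-terminal free ends may deviate by at most the
  tolerance ``e`` (default 10 nt);
* locus — transcripts clustered by exonic overlap; a reference locus counts
  as TP when at least one predicted transcript fully matches one of its
  transcripts (identical intron chain, terminal ends within tolerance).

Also reported: missed/novel exon and locus percentages and the count of
matching loci.  Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .core import TranscriptAnnotation


def _pct(num: int, den: int) -> float:
    if den == 0:
        return 0.0
    return float(Decimal(100.0 * num / den).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class LevelStats:
    """TP/FP/FN at one level.  At the locus level the TP counts on the
    reference side (matched reference loci) and the predicted side (matched
    predicted loci) can differ — e.g. two reference loci matched by one
    predicted locus — so ``tp_pred`` carries the predicted-side count used
    for precision; it defaults to ``tp``."""

    tp: int
    fp: int
    fn: int
    tp_pred: int | None = None

    @property
    def sensitivity(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def precision(self) -> float:
        tp = self.tp if self.tp_pred is None else self.tp_pred
        return _pct(tp, tp + self.fp)


@dataclass
class EvalReport:
    base: LevelStats
    exon: LevelStats
    locus: LevelStats
    missed_exons_pct: float
    missed_loci_pct: float
    novel_exons_pct: float
    novel_loci_pct: float
    matching_loci: int
    tolerance_e: int

    def as_table(self) -> str:
        rows = [
            ("Missed exons", f"{self.missed_exons_pct}%"),
            ("Missed loci", f"{self.missed_loci_pct}%"),
            ("Novel exons", f"{self.novel_exons_pct}%"),
            ("Novel loci", f"{self.novel_loci_pct}%"),
            ("Matching loci", str(self.matching_loci)),
        ]
        lines = ["metric\tvalue"]
        lines += [f"{k}\t{v}" for k, v in rows]
        lines.append("level\tsensitivity\tprecision")
        for level in ("base", "exon", "locus"):
            st: LevelStats = getattr(self, level)
            lines.append(f"{level}\t{st.sensitivity}\t{st.precision}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _merged_exon_intervals(
    transcripts: list[TranscriptAnnotation],
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in transcripts:
        by_key.setdefault((t.scaffold, t.strand), []).extend(t.exons)
    merged = {}
    for key, ivs in by_key.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[key] = out
    return merged


def _interval_list_intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class _Exon:
    scaffold: str
    strand: str
    start: int
    end: int


def _unique_exons(
    transcripts: list[TranscriptAnnotation],
) -> tuple[list[_Exon], dict[_Exon, tuple[bool, bool]]]:
    """Unique exons plus (start_free, end_free) flags (terminal in any
    transcript)."""
    flags: dict[_Exon, list[bool]] = {}
    for t in transcripts:
        for idx, (s, e) in enumerate(t.exons):
            ex = _Exon(t.scaffold, t.strand, s, e)
            f = flags.setdefault(ex, [False, False])
            if idx == 0:
                f[0] = True
            if idx == len(t.exons) - 1:
                f[1] = True
    exons = sorted(flags, key=lambda x: (x.scaffold, x.strand, x.start, x.end))
    return exons, {k: (v[0], v[1]) for k, v in flags.items()}


def _exon_match(
    p: _Exon, pf: tuple[bool, bool], r: _Exon, rf: tuple[bool, bool], e: int
) -> bool:
    if p.scaffold != r.scaffold or p.strand != r.strand:
        return False
    start_ok = p.start == r.start or (pf[0] and rf[0] and abs(p.start - r.start) <= e)
    end_ok = p.end == r.end or (pf[1] and rf[1] and abs(p.end - r.end) <= e)
    return start_ok and end_ok


def _max_matching(adj: list[list[int]], n_right: int) -> int:
    """Kuhn's augmenting-path maximum bipartite matching (sizes are small)."""
    match_right = [-1] * n_right

    def try_augment(u: int, seen: list[bool]) -> bool:
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                if match_right[v] == -1 or try_augment(match_right[v], seen):
                    match_right[v] = u
                    return True
        return False

    size = 0
    for u in range(len(adj)):
        if try_augment(u, [False] * n_right):
            size += 1
    return size


def _transcript_match(p: TranscriptAnnotation, r: TranscriptAnnotation, e: int) -> bool:
    """Full structural match: identical intron chain, terminal free ends
    within the tolerance."""
    if p.scaffold != r.scaffold or p.strand != r.strand:
        return False
    if len(p.exons) != len(r.exons):
        return False
    pe, re_ = p.exons, r.exons
    if abs(pe[0][0] - re_[0][0]) > e or abs(pe[-1][1] - re_[-1][1]) > e:
        return False
    # internal boundaries exact
    for i in range(len(pe)):
        if i > 0 and pe[i][0] != re_[i][0]:
            return False
        if i < len(pe) - 1 and pe[i][1] != re_[i][1]:
            return False
    return True


def _cluster_loci(transcripts: list[TranscriptAnnotation]) -> list[list[TranscriptAnnotation]]:
    """Connected components of transcripts linked by exonic overlap
    (same scaffold and strand)."""
    n = len(transcripts)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = transcripts[i], transcripts[j]
            if a.scaffold != b.scaffold or a.strand != b.strand:
                continue
            if any(
                min(e1, e2) > max(s1, s2)
                for s1, e1 in a.exons
                for s2, e2 in b.exons
            ):
                union(i, j)
    groups: dict[int, list[TranscriptAnnotation]] = {}
    for i, t in enumerate(transcripts):
        groups.setdefault(find(i), []).append(t)
    return list(groups.values())


# ---------------------------------------------------------------------------
# the comparison
# ---------------------------------------------------------------------------

def compare(
    predicted: list[TranscriptAnnotation],
    reference: list[TranscriptAnnotation],
    tolerance_e: int = 10,
) -> EvalReport:
    """Compare a predicted annotation against a reference."""
    if tolerance_e < 0:
        raise ValueError("tolerance_e must be >= 0")

    # --- base level -------------------------------------------------------
    pred_iv = _merged_exon_intervals(predicted)
    ref_iv = _merged_exon_intervals(reference)
    pred_bases = sum(e - s for ivs in pred_iv.values() for s, e in ivs)
    ref_bases = sum(e - s for ivs in ref_iv.values() for s, e in ivs)
    shared = sum(
        _interval_list_intersection(pred_iv[k], ref_iv[k])
        for k in pred_iv.keys() & ref_iv.keys()
    )
    base = LevelStats(tp=shared, fp=pred_bases - shared, fn=ref_bases - shared)

    # --- exon level -------------------------------------------------------
    pred_ex, pred_flags = _unique_exons(predicted)
    ref_ex, ref_flags = _unique_exons(reference)
    adj = [
        [
            j
            for j, r in enumerate(ref_ex)
            if _exon_match(p, pred_flags[p], r, ref_flags[r], tolerance_e)
        ]
        for p in pred_ex
    ]
    exon_tp = _max_matching(adj, len(ref_ex))
    exon = LevelStats(tp=exon_tp, fp=len(pred_ex) - exon_tp, fn=len(ref_ex) - exon_tp)

    def _overlaps_any(x: _Exon, ivs: dict) -> bool:
        merged = ivs.get((x.scaffold, x.strand), [])
        return any(min(e, x.end) > max(s, x.start) for s, e in merged)

    missed_exons = sum(1 for r in ref_ex if not _overlaps_any(r, pred_iv))
    novel_exons = sum(1 for p in pred_ex if not _overlaps_any(p, ref_iv))

    # --- locus level ------------------------------------------------------
    ref_loci = _cluster_loci(reference)
    pred_loci = _cluster_loci(predicted)
    matched_ref_loci = sum(
        1
        for locus in ref_loci
        if any(_transcript_match(p, r, tolerance_e) for r in locus for p in predicted)
    )
    matched_pred_loci = sum(
        1
        for locus in pred_loci
        if any(_transcript_match(p, r, tolerance_e) for p in locus for r in reference)
    )
    locus = LevelStats(
        tp=matched_ref_loci,
        fp=len(pred_loci) - matched_pred_loci,
        fn=len(ref_loci) - matched_ref_loci,
        tp_pred=matched_pred_loci,
    )

    def _locus_has_overlap(locus_ts: list[TranscriptAnnotation], ivs: dict) -> bool:
        return any(
            _overlaps_any(_Exon(t.scaffold, t.strand, s, e), ivs)
            for t in locus_ts
            for s, e in t.exons
        )

    missed_loci = sum(1 for l in ref_loci if not _locus_has_overlap(l, pred_iv))
    novel_loci = sum(1 for l in pred_loci if not _locus_has_overlap(l, ref_iv))

    return EvalReport(
        base=base,
        exon=exon,
        locus=locus,
        missed_exons_pct=_pct(missed_exons, len(ref_ex)),
        missed_loci_pct=_pct(missed_loci, len(ref_loci)),
        novel_exons_pct=_pct(novel_exons, len(pred_ex)),
        novel_loci_pct=_pct(novel_loci, len(pred_loci)),
        matching_loci=matched_ref_loci,
        tolerance_e=tolerance_e,
    )
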