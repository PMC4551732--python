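"""Merging of half-coverage haplotype scaffolds into the primary assembly.

Highly heterozygous regions of a diploid genome often assemble twice: once
inside a long scaffold and once as a standalone short scaffold ("haplotig")
at roughly half the expected read depth.  A haplotig is merged into a longer
scaffold when it aligns fully (coverage > 90 % of the haplotig and < 500 bp
left uncovered) to a significantly less covered region of that scaffold with
high sequence identity (> 95 %).  All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from lepcompgen.io import ScaffoldRecord

__all__ = [
    "AlignmentHit",
    "MergeDecision",
    "semiglobal_align",
    "locate_and_align",
    "classify_candidates",
    "merge_decision",
    "apply_merges",
    "find_merges",
    "assembly_n50",
]


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    query_cov_fraction: float
    query_uncovered_bp: int
    identity: float
    target_interval: tuple[int, int]
    target_region_depth: float | None = None


@dataclass
class MergeDecision:
    hit: AlignmentHit
    candidate_ok: bool
    coverage_ok: bool
    uncovered_ok: bool
    identity_ok: bool
    target_depth_ok: bool

    @property
    def merge(self) -> bool:
        return (
            self.candidate_ok
            and self.coverage_ok
            and self.uncovered_ok
            and self.identity_ok
            and self.target_depth_ok
        )


def semiglobal_align(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -2,
    gap: int = -2,
    max_cells: int = 300_000_000,
) -> AlignmentHit:
    """Best semi-global alignment of ``query`` inside ``target``.

    End gaps on the target are free; end gaps on the query are penalized, so
    a query that matches only part of the target region scores its unmatched
    tail.  Reported metrics: ``identity`` = matches / aligned columns (all
    columns of the alignment path), ``query_cov_fraction`` = query bases
    aligned against target bases (match or mismatch columns) / query length.

    A plain affine-free dynamic program over the full ``(n+1) x (m+1)``
    matrix; inputs are capped at ``max_cells`` cells — pre-locate long
    targets with :func:`locate_and_align`.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        raise ValueError("sequences must be non-empty")
    if (n + 1) * (m + 1) > max_cells:
        raise ValueError("alignment too large; use locate_and_align for long targets")

    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)

    prev = np.zeros(m + 1, dtype=np.int64)  # free leading target gap
    # traceback: 0 = diag, 1 = up (gap in target), 2 = left (gap in query)
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    idx = np.arange(m + 1, dtype=np.int64)
    gap_ramp = gap * idx
    for i in range(1, n + 1):
        sub = np.where(t == q[i - 1], match, mismatch).astype(np.int64)
        b = np.empty(m + 1, dtype=np.int64)
        b[0] = gap * i
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        np.maximum(diag, up, out=b[1:])
        # left moves: cur[j] = max_{j' <= j} (b[j'] + gap*(j-j')); linear gap
        # cost lets a running max over (b[j'] - gap*j') replace the scan
        adj = b - gap_ramp
        acc = np.maximum.accumulate(adj)
        cur = acc + gap_ramp
        row = tb[i]
        row[1:] = np.where(diag >= up, 0, 1)
        row[adj < acc] = 2
        prev = cur

    j = int(np.argmax(prev))  # free trailing target gap
    i = n
    matches = columns = aligned_q = 0
    end_j = j
    while i > 0:
        move = tb[i, j] if j > 0 else 1
        if move == 0:
            columns += 1
            aligned_q += 1
            if q[i - 1] == t[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif move == 1:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    cov = aligned_q / n
    return AlignmentHit(
        query_id="query",
        target_id="target",
        query_cov_fraction=cov,
        query_uncovered_bp=int(round((1 - cov) * n)),
        identity=matches / columns if columns else 0.0,
        target_interval=(j, end_j),
    )


def _hit_from_cigar(cigar: str, qlen: int) -> tuple[float, float, int]:
    """(identity, coverage, aligned target span) from an extended cigar."""
    matches = columns = aligned_q = tspan = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        columns += k
        if ch == "=":
            matches += k
            aligned_q += k
            tspan += k
        elif ch == "X":
            aligned_q += k
            tspan += k
        elif ch == "D":  # gap in query, target bases consumed
            tspan += k
        # "I": gap in target, query bases consumed but not aligned to target
    return matches / columns, aligned_q / qlen, tspan


def locate_and_align(
    query: ScaffoldRecord, target: ScaffoldRecord, margin_frac: float = 0.25,
    max_cells: int = 30_000_000,
) -> AlignmentHit:
    """Seed-and-extend wrapper for long targets.

    An edit-distance scan (edlib, infix mode) locates the best-matching
    region of the target; :func:`semiglobal_align` then computes identity
    and coverage on that region plus a margin, with coordinates mapped back
    to the full target.  When even the windowed matrix would exceed
    ``max_cells``, identity and coverage are taken from the edit-distance
    alignment path itself, which for the high-identity alignments this
    module cares about agrees with the scoring DP to well within the
    decision thresholds.
    """
    res = edlib.align(query.sequence, target.sequence, mode="HW", task="path")
    if not res["locations"]:
        raise ValueError("no alignment location found")
    loc_s, loc_e = res["locations"][0]
    margin = int(margin_frac * query.length) + 50
    ws = max(0, loc_s - margin)
    we = min(target.length, loc_e + 1 + margin)
    if (query.length + 1) * (we - ws + 1) > max_cells:
        identity, cov, _ = _hit_from_cigar(res["cigar"], query.length)
        return AlignmentHit(
            query_id=query.id,
            target_id=target.id,
            query_cov_fraction=cov,
            query_uncovered_bp=int(round((1 - cov) * query.length)),
            identity=identity,
            target_interval=(loc_s, loc_e + 1),
        )
    hit = semiglobal_align(query.sequence, target.sequence[ws:we])
    s, e = hit.target_interval
    hit.query_id = query.id
    hit.target_id = target.id
    hit.target_interval = (ws + s, ws + e)
    return hit


def assembly_n50(lengths: list[int]) -> int:
    """Scaffold N50: length at which the cumulative sum reaches half the total."""
    if not lengths:
        raise ValueError("empty assembly")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return L
    return 0  # unreachable


def classify_candidates(
    assembly: list[ScaffoldRecord],
    scaffold_depths: dict[str, float],
    hom_depth: float,
    depth_band: tuple[float, float] = (0.3, 0.75),
) -> list[str]:
    """Haplotig candidates: short scaffolds at roughly half the diploid depth.

    A scaffold qualifies when its mean depth falls within
    ``depth_band x hom_depth`` (default 0.3-0.75, bracketing the
    half-coverage signature) and its length is below the assembly N50.
    """
    n50 = assembly_n50([rec.length for rec in assembly])
    out = []
    for rec in assembly:
        d = scaffold_depths[rec.id]
        if depth_band[0] * hom_depth <= d <= depth_band[1] * hom_depth and rec.length < n50:
            out.append(rec.id)
    return out


def merge_decision(
    hit: AlignmentHit,
    candidate_ok: bool,
    hom_depth: float,
    cov_thresh: float = 0.90,
    unc_thresh: int = 500,
    id_thresh: float = 0.95,
    depth_frac: float = 0.75,
) -> MergeDecision:
    """Apply the merge rule to an alignment hit.

    coverage > ``cov_thresh``, uncovered < ``unc_thresh`` bp, identity >
    ``id_thresh`` and target-region depth < ``depth_frac`` x diploid depth —
    all strict.
    """
    for name, v in (("cov_thresh", cov_thresh), ("id_thresh", id_thresh)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    depth_ok = (
        hit.target_region_depth is not None
        and hit.target_region_depth < depth_frac * hom_depth
    )
    return MergeDecision(
        hit=hit,
        candidate_ok=candidate_ok,
        coverage_ok=hit.query_cov_fraction > cov_thresh,
        uncovered_ok=hit.query_uncovered_bp < unc_thresh,
        identity_ok=hit.identity > id_thresh,
        target_depth_ok=depth_ok,
    )


def apply_merges(
    assembly: list[ScaffoldRecord], decisions: list[MergeDecision]
) -> tuple[list[ScaffoldRecord], list[tuple[str, str, tuple[int, int]]]]:
    """Remove merged haplotigs from the scaffold set.

    When a haplotig has several positive decisions the highest identity wins
    (ties: longer target, then lexicographic target id).  A scaffold that was
    itself merged away cannot serve as a target; a circular request (two
    scaffolds each merging into the other) raises ``ValueError``.
    """
    lengths = {rec.id: rec.length for rec in assembly}
    present = set(lengths)
    positive = [
        d for d in decisions
        if d.merge and d.hit.query_id in present and d.hit.target_id in present
    ]
    by_query: dict[str, list[MergeDecision]] = {}
    for d in positive:
        by_query.setdefault(d.hit.query_id, []).append(d)

    chosen: dict[str, MergeDecision] = {}
    for qid, ds in by_query.items():
        ds.sort(
            key=lambda d: (-d.hit.identity, -lengths[d.hit.target_id], d.hit.target_id)
        )
        chosen[qid] = ds[0]

    for qid, d in chosen.items():
        tid = d.hit.target_id
        if tid in chosen and chosen[tid].hit.target_id == qid:
            raise ValueError(f"circular merge request between {qid} and {tid}")

    merged_ids = set(chosen)
    report = []
    for qid in sorted(chosen):
        d = chosen[qid]
        if d.hit.target_id in merged_ids:
            continue  # target consumed by its own merge
        report.append((qid, d.hit.target_id, d.hit.target_interval))
    kept = {qid for qid, _, _ in report}
    merged_assembly = [rec for rec in assembly if rec.id not in kept]
    return merged_assembly, report


def find_merges(
    assembly: list[ScaffoldRecord],
    scaffold_depths: dict[str, float],
    coverage: list[tuple[str, int, int, float]],
    hom_depth: float,
    **thresholds,
) -> tuple[list[ScaffoldRecord], list[tuple[str, str, tuple[int, int]]]]:
    """End-to-end haplotig merging: classify, align, decide, apply.

    Each candidate haplotig is aligned against every longer non-candidate
    scaffold; the target-region depth is the mean of coverage windows
    overlapping the aligned interval.
    """
    candidates = set(classify_candidates(assembly, scaffold_depths, hom_depth))
    targets = [rec for rec in assembly if rec.id not in candidates]
    by_id = {rec.id: rec for rec in assembly}
    cov_by_scf: dict[str, list[tuple[int, int, float]]] = {}
    for scf, s, e, d in coverage:
        cov_by_scf.setdefault(scf, []).append((s, e, d))

    decisions = []
    for qid in sorted(candidates):
        query = by_id[qid]
        for target in targets:
            if target.length <= query.length:
                continue
            hit = locate_and_align(query, target)
            s, e = hit.target_interval
            wins = [
                (min(e, we) - max(s, ws), d)
                for ws, we, d in cov_by_scf.get(target.id, [])
                if ws < e and we > s
            ]
            if wins:
                wtot = sum(w for w, _ in wins)
                hit.target_region_depth = sum(w * d for w, d in wins) / wtot
            decisions.append(merge_decision(hit, candidate_ok=True, hom_depth=hom_depth, **thresholds))
    return apply_merges(assembly, decisions)
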