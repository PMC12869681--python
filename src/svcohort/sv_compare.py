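"""Pairwise SV similarity, one-to-one callset matching, and cohort collapsing.

Two calls are considered the same event when their sequence similarity and
size similarity both clear a threshold and their start positions are within
a maximum distance. Collapsing consolidates such near-identical calls across
samples into a single cohort site, keeping the highest-quality call as the
site representative.

Sequence similarity is 1 - editdistance / max(len); size similarity is the
min/max length ratio. Both are symmetric and bounded in [0, 1].
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import edlib

if TYPE_CHECKING:  # pragma: no cover
    from svcohort.sv_model import SVRecord


@dataclass(frozen=True)
class MatchParams:
    """Thresholds deciding whether two SV calls represent the same event."""

    seq_sim_min: float = 0.95
    size_sim_min: float = 0.95
    max_dist: int = 1000
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.seq_sim_min <= 1 and 0 <= self.size_sim_min <= 1):
            raise ValueError("similarity thresholds must be in [0, 1]")
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")


# replicate-concordance comparison: any best match within the window is
# considered, the similarity cut is applied afterwards
PERMISSIVE = MatchParams(seq_sim_min=0.0, size_sim_min=0.0, max_dist=1000)


@dataclass(frozen=True)
class SVMatch:
    id_a: str
    id_b: str
    pct_seq_similarity: float
    pct_size_similarity: float
    dist: int
    is_match: bool


def edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def seq_similarity(a: str, b: str) -> float:
    """1 - editdistance(a, b) / max(len); 1.0 when both are empty."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / m


def size_similarity(len_a: int, len_b: int) -> float:
    """min/max length ratio; 1.0 iff equal."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("lengths must be positive")
    return min(len_a, len_b) / max(len_a, len_b)


def match_pair(a: "SVRecord", b: "SVRecord", p: MatchParams) -> SVMatch:
    """Compare two SV records under the given thresholds.

    For same-type pairs the comparison is over each record's variant
    sequence (deleted bases, inserted bases, or inverted span); records on
    different chromosomes never match.
    """
    dist = abs(a.start - b.start)
    if a.chrom != b.chrom:
        return SVMatch(a.record_id, b.record_id, 0.0, 0.0, dist, False)
    if a.svtype == b.svtype:
        seq_sim = seq_similarity(a.variant_sequence(), b.variant_sequence())
    else:
        seq_sim = seq_similarity(a.alt_allele, b.alt_allele)
    size_sim = size_similarity(max(a.svlen, 1), max(b.svlen, 1))
    ok = (
        seq_sim >= p.seq_sim_min
        and size_sim >= p.size_sim_min
        and dist <= p.max_dist
        and (a.svtype == b.svtype or not p.require_same_type)
    )
    return SVMatch(a.record_id, b.record_id, seq_sim, size_sim, dist, ok)


@dataclass
class MatchResult:
    matches: list[SVMatch]
    unmatched_a: list[str]
    unmatched_b: list[str]


def match_callsets(A: Sequence["SVRecord"], B: Sequence["SVRecord"],
                   p: MatchParams = MatchParams()) -> MatchResult:
    """Greedy one-to-one matching between two callsets.

    All same-chromosome candidate pairs within ``max_dist`` that satisfy the
    match predicate are ranked by (descending sequence similarity, descending
    size similarity, ascending distance, lexicographic record ids) and
    assigned greedily so each record participates in at most one match.
    """
    candidates: list[SVMatch] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, b in enumerate(B):
        by_chrom.setdefault(b.chrom, []).append((b.start, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for i, a in enumerate(A):
        nearby = by_chrom.get(a.chrom, [])
        lo = bisect.bisect_left(nearby, (a.start - p.max_dist, -1))
        hi = bisect.bisect_right(nearby, (a.start + p.max_dist, len(B)))
        for _, j in nearby[lo:hi]:
            m = match_pair(a, B[j], p)
            if m.is_match:
                candidates.append(m)
    candidates.sort(key=lambda m: (-m.pct_seq_similarity, -m.pct_size_similarity,
                                   m.dist, m.id_a, m.id_b))
    used_a: set[str] = set()
    used_b: set[str] = set()
    chosen: list[SVMatch] = []
    for m in candidates:
        if m.id_a in used_a or m.id_b in used_b:
            continue
        chosen.append(m)
        used_a.add(m.id_a)
        used_b.add(m.id_b)
    unmatched_a = [a.record_id for a in A if a.record_id not in used_a]
    unmatched_b = [b.record_id for b in B if b.record_id not in used_b]
    return MatchResult(chosen, unmatched_a, unmatched_b)


def _require_sorted(records: Sequence["SVRecord"]) -> None:
    keys = [(r.chrom, r.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, start)")


def collapse(records: Sequence["SVRecord"], p: MatchParams = MatchParams(),
             ) -> tuple[list["SVRecord"], dict[str, str]]:
    """Consolidate near-identical calls across samples into cohort sites.

    Greedy star clustering with a keep-max-qual representative: records are
    processed in descending quality (ties by chrom, start, record id); each
    record either joins the first existing seed it matches (per ``p``,
    compared against the seed itself, never chained through members) or
    founds a new site. Returns the surviving seed records, ordered by
    (chrom, start), and a record_id -> site record_id map.
    """
    _require_sorted(records)
    order = sorted(records, key=lambda r: (-r.qual, r.chrom, r.start, r.record_id))
    # per-chromosome seed index sorted by start for windowed lookup
    seed_starts: dict[str, list[tuple[int, int]]] = {}
    seeds: list["SVRecord"] = []
    cluster_map: dict[str, str] = {}
    for rec in order:
        nearby = seed_starts.setdefault(rec.chrom, [])
        lo = bisect.bisect_left(nearby, (rec.start - p.max_dist, -1))
        hi = bisect.bisect_right(nearby, (rec.start + p.max_dist, len(records)))
        assigned = None
        for _, si in sorted(nearby[lo:hi], key=lambda t: t[1]):  # seed creation order
            if match_pair(seeds[si], rec, p).is_match:
                assigned = si
                break
        if assigned is None:
            seeds.append(rec)
            si = len(seeds) - 1
            bisect.insort(nearby, (rec.start, si))
            assigned = si
        cluster_map[rec.record_id] = seeds[assigned].record_id
    sites = sorted(seeds, key=lambda r: (r.chrom, r.start, r.record_id))
    return sites, cluster_map
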