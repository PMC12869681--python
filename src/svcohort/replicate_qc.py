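"""Replicate-concordance QC and quality-threshold calibration.

Technical replicates (two sequencing runs of the same individual) provide an
internal truth set: a call reproduced in the partner run with over 70%
sequence and size similarity is *consistent*, anything else *inconsistent*.
The quality-score distributions of the two classes are then used to pick the
cohort-wide minimum quality threshold as the score that best segregates
consistent from inconsistent calls.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from svcohort.sv_compare import PERMISSIVE, MatchParams, match_callsets
from svcohort.sv_model import SampleMeta, SVRecord


@dataclass
class ReplicateReport:
    """Concordance summary for one replicate pair."""

    pair_id: str
    n_consistent: int
    n_inconsistent: int
    consistent_quals: list[float]
    inconsistent_quals: list[float]
    frac_highsim: float  # consistent matches with both similarities >= 0.95


def replicate_pairs(meta: Sequence[SampleMeta]) -> list[tuple[str, str]]:
    """All C(k, 2) sample pairs among replicates of each individual."""
    by_ind: dict[str, list[str]] = {}
    for m in meta:
        by_ind.setdefault(m.individual_id, []).append(m.sample_id)
    pairs = []
    for ind in sorted(by_ind):
        for a, b in itertools.combinations(sorted(by_ind[ind]), 2):
            pairs.append((a, b))
    return pairs


def classify_replicate_calls(a: Sequence[SVRecord], b: Sequence[SVRecord],
                             sim_min: float = 0.70,
                             match_params: MatchParams = PERMISSIVE,
                             highsim: float = 0.95,
                             pair_id: str | None = None) -> ReplicateReport:
    """Partition the calls of a replicate pair into consistent / inconsistent.

    Calls are first matched one-to-one within the positional window; a
    matched pair is consistent when BOTH similarities are strictly above
    ``sim_min``. Matched-below-threshold and unmatched calls are
    inconsistent. Every call of both callsets is counted exactly once.
    """
    ind_a = {r.sample_id for r in a}
    ind_b = {r.sample_id for r in b}
    if pair_id is None:
        pair_id = f"{'|'.join(sorted(ind_a))}~{'|'.join(sorted(ind_b))}"
    res = match_callsets(a, b, match_params)
    qual_a = {r.record_id: r.qual for r in a}
    qual_b = {r.record_id: r.qual for r in b}
    consistent_quals: list[float] = []
    inconsistent_quals: list[float] = []
    n_consistent = 0
    n_highsim = 0
    for m in res.matches:
        if m.pct_seq_similarity > sim_min and m.pct_size_similarity > sim_min:
            n_consistent += 1
            consistent_quals.extend((qual_a[m.id_a], qual_b[m.id_b]))
            if m.pct_seq_similarity >= highsim and m.pct_size_similarity >= highsim:
                n_highsim += 1
        else:
            inconsistent_quals.extend((qual_a[m.id_a], qual_b[m.id_b]))
    for rid in res.unmatched_a:
        inconsistent_quals.append(qual_a[rid])
    for rid in res.unmatched_b:
        inconsistent_quals.append(qual_b[rid])
    n_inconsistent = len(a) + len(b) - 2 * n_consistent
    return ReplicateReport(
        pair_id=pair_id,
        n_consistent=n_consistent,
        n_inconsistent=n_inconsistent,
        consistent_quals=consistent_quals,
        inconsistent_quals=inconsistent_quals,
        frac_highsim=n_highsim / n_consistent if n_consistent else 0.0,
    )


def calibrate_quality_threshold(consistent_quals: Sequence[float],
                                inconsistent_quals: Sequence[float],
                                grid: float = 1.0,
                                criterion: str = "youden") -> tuple[float, float]:
    """Grid-search the quality cutoff that best segregates the two classes.

    Returns ``(t, J)`` where ``t`` maximizes Youden's
    J(t) = P(consistent >= t) - P(inconsistent >= t)
    over the grid (ties broken toward the smallest t). ``criterion='ks'``
    maximizes |J| instead (two-sample KS statistic on the grid).
    """
    if len(consistent_quals) == 0 or len(inconsistent_quals) == 0:
        raise ValueError("both quality lists must be nonempty")
    cons = np.sort(np.asarray(consistent_quals, dtype=float))
    incons = np.sort(np.asarray(inconsistent_quals, dtype=float))
    lo = math.floor(min(cons[0], incons[0]))
    hi = math.ceil(max(cons[-1], incons[-1])) + grid
    ts = np.arange(lo, hi + grid / 2, grid)
    frac_cons = 1.0 - np.searchsorted(cons, ts, side="left") / len(cons)
    frac_incons = 1.0 - np.searchsorted(incons, ts, side="left") / len(incons)
    j = frac_cons - frac_incons
    if criterion == "ks":
        j = np.abs(j)
    elif criterion != "youden":
        raise ValueError(f"unknown criterion {criterion!r}")
    best = int(np.argmax(j))  # argmax returns the first (smallest t) maximum
    return float(ts[best]), float(j[best])


def apply_quality_filter(records: Sequence[SVRecord] | np.ndarray,
                         t: float = 50.0) -> tuple[list, int]:
    """Retain records (or raw quality scores) with qual >= t.

    Returns ``(passed, removed_count)``; conservation holds:
    ``len(records) == len(passed) + removed_count``.
    """
    if isinstance(records, np.ndarray):
        passed = list(records[records >= t])
    else:
        passed = [r for r in records if r.qual >= t]
    return passed, len(records) - len(passed)
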