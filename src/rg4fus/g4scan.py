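"""Putative RNA G-quadruplex (rG4) motif scanning.

A QGRS (quadruplex-forming G-rich sequence) is four G-runs of equal length
``g`` (the tetrad count) separated by three loops. The scanner enumerates
every placement satisfying the length constraints — overlapping candidates
are all reported, since downstream analysis consumes presence/absence — and
ranks them with a surrogate G-score favouring more tetrads, shorter spans
and more evenly sized loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import SequenceRecord

__all__ = ["ScanParams", "G4Candidate", "find_candidates", "score_candidate",
           "classify_panel"]


@dataclass(frozen=True)
class ScanParams:
    """Scan constraints: motif span <= max_length nt, G-runs of >= min_group
    guanines, loops of loop_min..loop_max nt."""

    max_length: int = 30
    min_group: int = 2
    loop_min: int = 0
    loop_max: int = 36

    def __post_init__(self) -> None:
        if self.min_group < 2:
            raise ValueError("min_group must be >= 2")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("require 0 <= loop_min <= loop_max")
        if self.max_length < 4 * self.min_group:
            raise ValueError("max_length must allow four G-runs")


@dataclass(frozen=True)
class G4Candidate:
    """One enumerated quadruplex placement: start offset, G-run length g,
    three loop lengths, total span and surrogate score."""

    start: int
    group_size: int
    loops: tuple[int, int, int]
    length: int
    score: int

    def __post_init__(self) -> None:
        if self.length != 4 * self.group_size + sum(self.loops):
            raise ValueError("length must equal 4*g + sum(loops)")


def score_candidate(group_size: int, loops: tuple[int, int, int], length: int,
                    params: ScanParams) -> int:
    """Surrogate G-score: 10*(g - min_group) + (max_length - L) - loop spread.

    Higher for more tetrads, shorter spans, and more equal loops; used only
    to rank candidates (presence/absence is the consumed signal).
    """
    if group_size < params.min_group:
        raise ValueError("group_size below min_group")
    if length > params.max_length:
        raise ValueError("candidate longer than max_length")
    for loop in loops:
        if not (params.loop_min <= loop <= params.loop_max):
            raise ValueError("loop length outside bounds")
    return (10 * (group_size - params.min_group)
            + (params.max_length - length)
            - (max(loops) - min(loops)))


def find_candidates(record: SequenceRecord,
                    params: ScanParams = ScanParams()) -> list[G4Candidate]:
    """Enumerate all quadruplex placements in a sequence.

    Exhaustive over (start, g, l1, l2, l3) tuples subject to the scan
    constraints; G-runs longer than g yield candidates at multiple registers,
    deduplicated only on identical tuples. Sorted by (start, -score).
    """
    seq = record.sequence
    n = len(seq)
    # g_run[i] = length of the maximal run of G starting at i
    g_run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        g_run[i] = g_run[i + 1] + 1 if seq[i] == "G" else 0

    out: list[G4Candidate] = []
    seen: set[tuple[int, int, tuple[int, int, int]]] = set()
    g_max = params.max_length // 4
    for start in range(n):
        for g in range(params.min_group, g_max + 1):
            if g_run[start] < g:
                continue
            budget = params.max_length - 4 * g  # total loop length available
            if budget < 3 * params.loop_min:
                continue
            p1 = start + g
            for l1 in range(params.loop_min,
                            min(params.loop_max, budget - 2 * params.loop_min) + 1):
                p2 = p1 + l1
                if p2 + g > n or g_run[p2] < g:
                    continue
                rem1 = budget - l1
                p3 = p2 + g
                for l2 in range(params.loop_min,
                                min(params.loop_max, rem1 - params.loop_min) + 1):
                    q = p3 + l2
                    if q + g > n or g_run[q] < g:
                        continue
                    rem2 = rem1 - l2
                    p4 = q + g
                    for l3 in range(params.loop_min,
                                    min(params.loop_max, rem2) + 1):
                        r = p4 + l3
                        if r + g > n or g_run[r] < g:
                            continue
                        loops = (l1, l2, l3)
                        key = (start, g, loops)
                        if key in seen:
                            continue
                        seen.add(key)
                        length = 4 * g + l1 + l2 + l3
                        out.append(G4Candidate(
                            start, g, loops, length,
                            score_candidate(g, loops, length, params)))
    out.sort(key=lambda c: (c.start, -c.score, c.loops))
    return out


def classify_panel(records: list[SequenceRecord],
                   params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Classify a panel of RNAs as rG4-positive/negative.

    ``has_rG4`` is true iff the scanner finds any candidate; the best
    candidate (highest score, ties by smallest start) is reported alongside.
    """
    rows = []
    for rec in records:
        cands = find_candidates(rec, params)
        if cands:
            best = max(cands, key=lambda c: (c.score, -c.start))
            rows.append({
                "name": rec.name, "has_rG4": True, "start": best.start,
                "g": best.group_size, "loops": ",".join(map(str, best.loops)),
                "length": best.length, "score": best.score,
            })
        else:
            rows.append({
                "name": rec.name, "has_rG4": False, "start": pd.NA,
                "g": pd.NA, "loops": pd.NA, "length": pd.NA, "score": pd.NA,
            })
    return pd.DataFrame(
        rows, columns=["name", "has_rG4", "start", "g", "loops", "length", "score"]
    )
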