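"""Transcriptome-interval enrichment between soluble- and droplet-phase
FUS interactomes.

Scored rG4 regions (30-nt intervals carrying a "G4 Probability" — the
fraction of reads with reverse-transcription stops in an rG4-seq assay) are
stratified into low/medium/high tertiles, intersected with the two phase
interactomes, and summarised by an enrichment score: the ratio of a region's
occurrence in the soluble interactome to its occurrence in the droplet
interactome. Significance of overlap counts is assessed by shuffling either
set across the genome and computing an empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomeTable, GenomicInterval

__all__ = [
    "G4Region",
    "EnrichmentRecord",
    "PermutationResult",
    "count_overlaps",
    "stratify_by_probability",
    "phase_enrichment",
    "select_candidates",
    "shuffle_intervals",
    "permutation_test",
]

Stratum = Literal["low", "medium", "high"]


@dataclass(frozen=True)
class G4Region:
    """An rG4-seq region with its stability score ("G4 Probability")."""

    interval: GenomicInterval
    g4_probability: float
    stratum: Stratum | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.g4_probability <= 1.0):
            raise ValueError("g4_probability must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-region overlap counts in each phase and the soluble/droplet
    enrichment ratio (defined only for shared regions)."""

    region_id: str
    count_soluble: int
    count_droplet: int
    exclusivity: Literal["soluble_only", "droplet_only", "shared", "neither"]
    enrichment: float | None = None


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    null_counts: tuple[int, ...]
    n_shuffles: int
    empirical_p: float
    direction: str


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # data payload keeps duplicate intervals distinct (IntervalTree is a set)
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def count_overlaps(query: Sequence[GenomicInterval],
                   subject: Sequence[GenomicInterval],
                   min_bp: int = 1) -> np.ndarray:
    """Count subject intervals sharing >= min_bp bases with each query.

    Half-open overlap semantics (bedtools intersect -c); strand ignored.
    Queries on chromosomes absent from the subject simply count zero.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(subject)
    counts = np.zeros(len(query), dtype=int)
    for i, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = tree.overlap(q.start, q.end)
        counts[i] = sum(
            1 for h in hits
            if min(q.end, h.end) - max(q.start, h.begin) >= min_bp
        )
    return counts


def stratify_by_probability(regions: Sequence[G4Region]) -> list[G4Region]:
    """Assign low/medium/high strata as equal-size tertiles of G4 Probability.

    Regions are ordered ascending by score with stable tie order; group sizes
    differ by at most one, the extra members going to the lower strata.
    Returns new region objects in the sorted order.
    """
    n = len(regions)
    if n < 3:
        raise ValueError("stratification requires at least 3 regions")
    order = sorted(range(n), key=lambda i: regions[i].g4_probability)
    n_low = -(-n // 3)                     # ceil(n/3)
    n_med = -(-(n - n_low) // 2)           # ceil of the remainder's half
    out: list[G4Region] = []
    for rank, idx in enumerate(order):
        if rank < n_low:
            stratum: Stratum = "low"
        elif rank < n_low + n_med:
            stratum = "medium"
        else:
            stratum = "high"
        out.append(replace(regions[idx], stratum=stratum))
    return out


def phase_enrichment(regions: Sequence[G4Region],
                     soluble: Sequence[GenomicInterval],
                     droplet: Sequence[GenomicInterval]) -> list[EnrichmentRecord]:
    """Per-region soluble/droplet occurrence counts and enrichment score.

    Occurrence is the count of overlapping interactome intervals. The
    enrichment score count_soluble/count_droplet is computed only for regions
    present in both phases ("shared"); regions seen in one phase only are
    labelled soluble_only/droplet_only.
    """
    ivs = [r.interval for r in regions]
    c_sol = count_overlaps(ivs, soluble)
    c_drop = count_overlaps(ivs, droplet)
    records: list[EnrichmentRecord] = []
    for region, cs, cd in zip(regions, c_sol, c_drop):
        rid = region.interval.name or (
            f"{region.interval.chrom}:{region.interval.start}-{region.interval.end}"
        )
        if cs > 0 and cd > 0:
            records.append(EnrichmentRecord(rid, int(cs), int(cd), "shared",
                                            cs / cd))
        elif cs > 0:
            records.append(EnrichmentRecord(rid, int(cs), 0, "soluble_only"))
        elif cd > 0:
            records.append(EnrichmentRecord(rid, 0, int(cd), "droplet_only"))
        else:
            records.append(EnrichmentRecord(rid, 0, 0, "neither"))
    return records


def select_candidates(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Rank candidate inhibitor regions by soluble-phase preference.

    Soluble-exclusive regions come first, then shared regions by descending
    enrichment score; ties break on region id.
    """
    exclusive = sorted(
        (r for r in records if r.exclusivity == "soluble_only"),
        key=lambda r: r.region_id,
    )
    shared = sorted(
        (r for r in records if r.exclusivity == "shared"),
        key=lambda r: (-r.enrichment, r.region_id),
    )
    return exclusive + shared


def shuffle_intervals(intervals: Sequence[GenomicInterval],
                      genome: GenomeTable,
                      rng: np.random.Generator | int | None = None
                      ) -> list[GenomicInterval]:
    """Re-place each interval uniformly at random in the genome.

    Mirrors bedtools shuffle defaults: each interval lands independently on a
    chromosome drawn with probability proportional to length (among those it
    fits), start uniform in [0, chrom_len - interval_len]; lengths are
    preserved and shuffled intervals may overlap one another.
    """
    rng = np.random.default_rng(rng)
    chroms = list(genome.entries)
    lengths = np.array([genome.entries[c] for c in chroms], dtype=float)
    out: list[GenomicInterval] = []
    for iv in intervals:
        fits = lengths >= iv.length
        if not fits.any():
            raise ValueError(
                f"interval of length {iv.length} exceeds every chromosome"
            )
        p = np.where(fits, lengths, 0.0)
        p /= p.sum()
        ci = rng.choice(len(chroms), p=p)
        start = int(rng.integers(0, int(lengths[ci]) - iv.length + 1))
        out.append(GenomicInterval(chroms[ci], start, start + iv.length,
                                   iv.name, iv.score, iv.strand))
    return out


def permutation_test(set_a: Sequence[GenomicInterval],
                     set_b: Sequence[GenomicInterval],
                     genome: GenomeTable,
                     n_shuffles: int = 100,
                     direction: Literal["a", "b"] = "a",
                     rng: np.random.Generator | int | None = None
                     ) -> PermutationResult:
    """Permutation test for overlap enrichment between two interval sets.

    The observed statistic is the number of set A intervals with at least one
    base of overlap in set B. The null is built by re-placing the set named
    by ``direction`` across the genome ``n_shuffles`` times; the empirical
    p-value uses the (r+1)/(N+1) pseudocount estimator, so it is never zero,
    and tests the enrichment (upper) tail.
    """
    if not set_a or not set_b:
        raise ValueError("both interval sets must be non-empty")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if direction not in ("a", "b"):
        raise ValueError("direction must be 'a' or 'b'")
    rng = np.random.default_rng(rng)
    b_trees = _build_trees(set_b)

    def hits_in_b(query: Sequence[GenomicInterval]) -> int:
        n = 0
        for q in query:
            tree = b_trees.get(q.chrom)
            if tree is not None and tree.overlaps(q.start, q.end):
                n += 1
        return n

    observed = hits_in_b(set_a)
    null_counts: list[int] = []
    for _ in range(n_shuffles):
        if direction == "a":
            stat = hits_in_b(shuffle_intervals(set_a, genome, rng))
        else:
            stat = int((count_overlaps(set_a,
                                       shuffle_intervals(set_b, genome, rng))
                        > 0).sum())
        null_counts.append(stat)
    r = sum(1 for c in null_counts if c >= observed)
    p = (1 + r) / (n_shuffles + 1)
    return PermutationResult(observed, tuple(null_counts), n_shuffles, p,
                             direction)
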