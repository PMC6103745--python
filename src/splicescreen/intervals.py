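"""Genomic-interval statistics for CLIP-seq peak sets.

All coordinates are 0-based half-open (BED convention): intervals
(a, b) and (b, c) do not overlap.  The module covers the peak-level
analyses around an eCLIP experiment once peaks have been called:
significance filtering (p <= 1e-5 and fold-enrichment >= 8 by default),
counting overlap between two peak sets with a sorted sweep, a
permutation test of that overlap by random shuffling of one peak set
within chromosomes, assignment of peaks to transcript regions, and
annotation of skipped-exon events with peaks falling in the alternative
exon or its flanking introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeLayout",
    "Transcript",
    "RegionAnnotation",
    "filter_peaks",
    "count_overlap",
    "shuffle_intervals",
    "overlap_permutation_test",
    "assign_region",
    "annotate_events_with_peaks",
    "REGION_PRIORITY",
]

REGION_PRIORITY = ("CDS", "3UTR", "5UTR", "noncoding_exon", "intron", "intergenic")
EXONIC_REGIONS = ("CDS", "5UTR", "3UTR", "noncoding_exon")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional peak statistics."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."
    p_value: float = 1.0
    fold_enrichment: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeLayout:
    """Chromosome name -> length (bp)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome layout is empty")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass
class PeakSet:
    """A labelled collection of intervals, optionally genome-validated."""

    label: str
    intervals: list[GenomicInterval]
    genome: GenomeLayout | None = None

    def __post_init__(self) -> None:
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(f"peak on unknown chromosome {iv.chrom!r}")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"peak {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def filter_peaks(peaks: PeakSet, max_p: float = 1e-5, min_fold: float = 8.0) -> PeakSet:
    """Significant peaks: p_value <= max_p and fold_enrichment >= min_fold.

    Both boundaries are inclusive.
    """
    kept = [
        iv for iv in peaks.intervals if iv.p_value <= max_p and iv.fold_enrichment >= min_fold
    ]
    return PeakSet(label=peaks.label, intervals=kept, genome=peaks.genome)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into disjoint sorted runs."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > cummax[:-1]
    run_starts = np.flatnonzero(new_run)
    return s[run_starts], np.maximum.reduceat(e, run_starts)


def _count_hits(a_starts: np.ndarray, a_ends: np.ndarray,
                b_starts: np.ndarray, b_ends: np.ndarray) -> int:
    """How many A intervals touch a merged, disjoint, sorted B run.

    An A interval overlaps iff the last B run starting before A's end
    extends past A's start (runs are disjoint, so it is the only
    candidate).
    """
    if len(b_starts) == 0 or len(a_starts) == 0:
        return 0
    idx = np.searchsorted(b_starts, a_ends, side="left") - 1
    valid = idx >= 0
    hit = np.zeros(len(a_starts), dtype=bool)
    hit[valid] = b_ends[idx[valid]] > a_starts[valid]
    return int(hit.sum())


def _grouped_arrays(peaks: PeakSet, stranded: bool) -> dict[tuple, tuple[np.ndarray, np.ndarray]]:
    groups: dict[tuple, list[tuple[int, int]]] = {}
    for iv in peaks.intervals:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom, ".")
        groups.setdefault(key, []).append((iv.start, iv.end))
    return {
        k: (np.array([p[0] for p in v]), np.array([p[1] for p in v]))
        for k, v in groups.items()
    }


def count_overlap(peaks_a: PeakSet, peaks_b: PeakSet, stranded: bool = False) -> int:
    """Number of A intervals sharing >= 1 bp with any B interval.

    Half-open semantics; each A interval is counted at most once.  With
    ``stranded=True`` only same-strand overlaps count.  Sorted-sweep
    implementation, O((|A|+|B|) log |B|) per chromosome.
    """
    a_groups = _grouped_arrays(peaks_a, stranded)
    b_groups = {k: _merge_intervals(*v) for k, v in _grouped_arrays(peaks_b, stranded).items()}
    total = 0
    for key, (a_starts, a_ends) in a_groups.items():
        if key in b_groups:
            total += _count_hits(a_starts, a_ends, *b_groups[key])
    return total


def shuffle_intervals(peaks: PeakSet, genome: GenomeLayout, seed: int) -> PeakSet:
    """Randomly replace every interval within its own chromosome.

    Chromosome assignment and interval length are preserved; the new
    start is uniform on [0, chrom_length - length].  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for iv in peaks.intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        room = genome[iv.chrom] - len(iv)
        if room < 0:
            raise ValueError(f"interval longer than chromosome {iv.chrom!r}")
        start = int(rng.integers(0, room + 1))
        shuffled.append(replace(iv, start=start, end=start + len(iv)))
    return PeakSet(label=f"{peaks.label}_shuffled", intervals=shuffled, genome=genome)


def overlap_permutation_test(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    genome: GenomeLayout,
    n_perm: int = 999,
    seed: int = 0,
    stranded: bool = False,
) -> dict:
    """Enrichment test of peak-set overlap by shuffling the B set.

    Returns the observed overlap (A intervals touching B), the mean
    overlap across ``n_perm`` seeded shuffles of B, and the one-sided
    add-one p-value p = (1 + #{overlap* >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    observed = count_overlap(peaks_a, peaks_b, stranded=stranded)
    for iv in peaks_b.intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if len(iv) > genome[iv.chrom]:
            raise ValueError(f"interval longer than chromosome {iv.chrom!r}")
    # Array fast path: shuffling only moves starts within chromosomes, so
    # extract coordinates once and redraw starts vectorised per round.
    a_groups = _grouped_arrays(peaks_a, stranded)
    b_keys = [(iv.chrom, iv.strand) if stranded else (iv.chrom, ".") for iv in peaks_b.intervals]
    b_lengths = np.array([len(iv) for iv in peaks_b.intervals])
    room = np.array([genome[k[0]] for k in b_keys]) - b_lengths
    key_index: dict[tuple, np.ndarray] = {}
    for i, key in enumerate(b_keys):
        key_index.setdefault(key, []).append(i)  # type: ignore[arg-type]
    key_index = {k: np.array(v) for k, v in key_index.items()}
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        starts = rng.integers(0, room + 1)
        ends = starts + b_lengths
        total = 0
        for key, sel in key_index.items():
            if key in a_groups:
                m_starts, m_ends = _merge_intervals(starts[sel], ends[sel])
                total += _count_hits(*a_groups[key], m_starts, m_ends)
        nulls[i] = total
    p = (1 + int(np.sum(nulls >= observed))) / (n_perm + 1)
    return {
        "observed": observed,
        "null_mean": float(nulls.mean()),
        "p": p,
        "n_perm": n_perm,
    }


@dataclass(frozen=True)
class Transcript:
    """Ordered, non-overlapping exons of one transcript with region labels."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int, str], ...]  # (start, end, region label)

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end, label in self.exons:
            if label not in EXONIC_REGIONS:
                raise ValueError(f"unknown exon region label {label!r}")
            if start < prev_end:
                raise ValueError(f"exons of {self.transcript_id!r} overlap or are unsorted")
            if start >= end:
                raise ValueError("exon start must be < end")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class RegionAnnotation:
    """Transcript models used to assign peaks to genomic regions."""

    transcripts: list[Transcript]
    _by_chrom: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_chrom = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)


def assign_region(peak: GenomicInterval, annotation: RegionAnnotation) -> str:
    """Region label for a peak, by midpoint position and fixed priority.

    A peak hitting several features across overlapping transcripts gets
    the highest-priority label (CDS > 3UTR > 5UTR > noncoding exon >
    intron > intergenic).  Strand-aware when the peak has a strand.
    """
    mid = peak.midpoint
    found: set[str] = set()
    for tx in annotation._by_chrom.get(peak.chrom, []):
        if peak.strand != "." and tx.strand != peak.strand:
            continue
        span = tx.span
        if not span[0] <= mid < span[1]:
            continue
        label = "intron"
        for start, end, region in tx.exons:
            if start <= mid < end:
                label = region
                break
        found.add(label)
    for label in REGION_PRIORITY:
        if label in found:
            return label
    return "intergenic"


def annotate_events_with_peaks(
    events,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    flank_bp: int | None = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Flag skipped-exon events by peak presence in their splicing window.

    The window is the alternative exon plus both flanking introns, i.e.
    the contiguous span (upstream_exon.end, downstream_exon.start);
    ``flank_bp`` optionally caps each intronic flank at a distance from
    the exon.  Returns a per-event category in {A_only, B_only, both,
    neither} and the four-category summary counts.
    """

    def window(ev) -> tuple[int, int]:
        lo, hi = ev.upstream_exon[1], ev.downstream_exon[0]
        if flank_bp is not None:
            lo = max(lo, ev.exon_start - flank_bp)
            hi = min(hi, ev.exon_end + flank_bp)
        return lo, hi

    def hits(peaks: PeakSet, ev, lo: int, hi: int) -> bool:
        for iv in peaks.intervals:
            if iv.chrom == ev.chrom and iv.start < hi and iv.end > lo:
                return True
        return False

    categories: dict[str, str] = {}
    summary = {"A_only": 0, "B_only": 0, "both": 0, "neither": 0}
    for ev in events:
        lo, hi = window(ev)
        in_a = hits(peaks_a, ev, lo, hi)
        in_b = hits(peaks_b, ev, lo, hi)
        category = {
            (True, True): "both",
            (True, False): "A_only",
            (False, True): "B_only",
            (False, False): "neither",
        }[(in_a, in_b)]
        categories[ev.event_id] = category
        summary[category] += 1
    return categories, summary
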