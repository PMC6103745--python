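"""Percent-spliced-in (PSI) quantification and differential exon skipping.

PSI for a skipped-exon (SE) event is estimated from junction reads that
support inclusion (IC) versus skipping (SC) of the alternative exon,
normalised by the effective lengths of the two isoform forms:

    psi = (IC / lI) / (IC / lI + SC / lS)

with SE defaults lI=2 (two inclusion junctions) and lS=1 (one skipping
junction).  Events with too little evidence — group-wise IC+SC below a
floor of 10 — are removed before testing.  Differential splicing between
two groups is called on pooled counts with a two-sided Fisher's exact
test, Benjamini–Hochberg FDR, and a minimum |delta PSI| of 0.05.  This
pooled-count test is a declared, simpler substitute for the hierarchical
likelihood model of junction-count tools such as rMATS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr

__all__ = [
    "SpliceEvent",
    "JunctionCounts",
    "compute_psi",
    "psi_matrix",
    "filter_events",
    "differential_splicing",
    "tally_event_types",
    "shared_event_overlap",
    "EVENT_TYPES",
]

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")
DIRECTIONS = ("exclusion", "inclusion")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event (0-based half-open coordinates).

    For an SE event the geometry is
    ``upstream_exon.end <= exon_start < exon_end <= downstream_exon.start``;
    ``l_inc``/``l_skip`` are the effective lengths of the inclusion and
    skipping forms used to length-normalise PSI.
    """

    event_id: str
    gene: str
    etype: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    l_inc: int = 2
    l_skip: int = 1

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.l_inc < 1 or self.l_skip < 1:
            raise ValueError("effective lengths must be >= 1")
        if not (
            self.upstream_exon[0] < self.upstream_exon[1] <= self.exon_start
            < self.exon_end <= self.downstream_exon[0] < self.downstream_exon[1]
        ):
            raise ValueError(f"invalid SE geometry for event {self.event_id!r}")


@dataclass
class JunctionCounts:
    """Inclusion/skipping junction counts per event and sample.

    ``inclusion`` and ``skipping`` are aligned event x sample integer
    DataFrames; ``groups`` maps each sample to its group label.
    """

    inclusion: pd.DataFrame
    skipping: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.inclusion.index.equals(self.skipping.index) or not (
            self.inclusion.columns.equals(self.skipping.columns)
        ):
            raise ValueError("inclusion and skipping tables must be aligned")
        if (self.inclusion.to_numpy() < 0).any() or (self.skipping.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")
        unknown = set(self.groups) - set(self.inclusion.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out


def compute_psi(ic, sc, l_inc: float = 2, l_skip: float = 1):
    """Length-normalised percent spliced in; NaN when IC+SC is zero.

    psi = (IC/lI) / (IC/lI + SC/lS).  Swapping (IC, lI) with (SC, lS)
    maps psi to 1-psi.
    """
    ic = np.asarray(ic, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if np.any(ic < 0) or np.any(sc < 0):
        raise ValueError("counts must be non-negative")
    if np.any(np.asarray(l_inc) < 1) or np.any(np.asarray(l_skip) < 1):
        raise ValueError("effective lengths must be >= 1")
    inc_rate = ic / l_inc
    skip_rate = sc / l_skip
    denom = inc_rate + skip_rate
    with np.errstate(invalid="ignore"):
        psi = np.where(denom > 0, inc_rate / np.where(denom > 0, denom, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi) if denom > 0 else float("nan")
    return psi


def psi_matrix(counts: JunctionCounts, events: list[SpliceEvent] | None = None) -> pd.DataFrame:
    """Per-event, per-sample PSI table (NaN where an event has no reads)."""
    if events is not None:
        li = pd.Series({e.event_id: e.l_inc for e in events}).reindex(counts.inclusion.index)
        ls = pd.Series({e.event_id: e.l_skip for e in events}).reindex(counts.inclusion.index)
        if li.isna().any():
            raise ValueError("count table contains events without definitions")
        li = li.to_numpy()[:, None]
        ls = ls.to_numpy()[:, None]
    else:
        li, ls = 2, 1
    psi = compute_psi(counts.inclusion.to_numpy(), counts.skipping.to_numpy(), li, ls)
    return pd.DataFrame(psi, index=counts.inclusion.index, columns=counts.inclusion.columns)


def filter_events(
    counts: JunctionCounts,
    group1: str,
    group2: str,
    min_total: int = 10,
    scope: str = "group",
) -> pd.Index:
    """Events with enough junction evidence in both groups.

    ``scope='group'`` (default): the sum of IC+SC across a group's
    samples must reach ``min_total`` in *each* group (inclusive).
    ``scope='sample'``: every individual sample must reach the floor.
    """
    if scope not in ("group", "sample"):
        raise ValueError(f"unknown filter scope {scope!r}")
    total = counts.inclusion + counts.skipping
    keep = pd.Series(True, index=total.index)
    for group in (group1, group2):
        cols = counts.samples_in_group(group)
        if scope == "group":
            keep &= total[cols].sum(axis=1) >= min_total
        else:
            keep &= (total[cols] >= min_total).all(axis=1)
    return total.index[keep]


def differential_splicing(
    events: list[SpliceEvent],
    counts: JunctionCounts,
    group1: str,
    group2: str,
    min_total: int = 10,
    min_abs_dpsi: float = 0.05,
    alpha: float = 0.05,
    filter_scope: str = "group",
) -> pd.DataFrame:
    """Pooled-count differential splicing between two sample groups.

    Per retained event: group PSI from group-summed counts, delta PSI =
    group2 - group1, two-sided Fisher's exact p on the pooled 2x2 table
    [[IC1, SC1], [IC2, SC2]], BH FDR across tested events.  An event is
    ``significant`` iff ``fdr <= alpha`` and ``|delta_psi| >= min_abs_dpsi``;
    ``direction`` is ``exclusion`` when delta PSI is negative.
    """
    by_id = {e.event_id: e for e in events}
    missing = set(counts.inclusion.index) - set(by_id)
    if missing:
        raise ValueError(f"count table contains undefined events: {sorted(missing)[:3]}...")
    kept = filter_events(counts, group1, group2, min_total, scope=filter_scope)
    cols1 = counts.samples_in_group(group1)
    cols2 = counts.samples_in_group(group2)
    rows = []
    for eid in kept:
        ev = by_id[eid]
        ic1 = int(counts.inclusion.loc[eid, cols1].sum())
        sc1 = int(counts.skipping.loc[eid, cols1].sum())
        ic2 = int(counts.inclusion.loc[eid, cols2].sum())
        sc2 = int(counts.skipping.loc[eid, cols2].sum())
        psi1 = compute_psi(ic1, sc1, ev.l_inc, ev.l_skip)
        psi2 = compute_psi(ic2, sc2, ev.l_inc, ev.l_skip)
        _, p = stats.fisher_exact([[ic1, sc1], [ic2, sc2]], alternative="two-sided")
        dpsi = psi2 - psi1
        rows.append(
            {
                "event_id": eid,
                "gene": ev.gene,
                "etype": ev.etype,
                "psi_group1": psi1,
                "psi_group2": psi2,
                "delta_psi": dpsi,
                "p": p,
                "direction": "exclusion" if dpsi < 0 else "inclusion",
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene", "etype", "psi_group1", "psi_group2",
            "delta_psi", "p", "direction",
        ],
    )
    if len(result):
        result["fdr"] = bh_fdr(result["p"].to_numpy())
        result["significant"] = (result["fdr"] <= alpha) & (
            result["delta_psi"].abs() >= min_abs_dpsi
        )
    else:
        result["fdr"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result.set_index("event_id")


def tally_event_types(results: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """Complete etype x direction contingency table (zero cells included)."""
    if significant_only and "significant" in results.columns:
        results = results[results["significant"]]
    table = pd.DataFrame(0, index=list(EVENT_TYPES), columns=list(DIRECTIONS), dtype=int)
    if len(results):
        counts = results.groupby(["etype", "direction"]).size()
        for (etype, direction), n in counts.items():
            table.loc[etype, direction] = n
    table.index.name = "etype"
    return table


def shared_event_overlap(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[int, float]:
    """Overlap of two event sets and its one-sided Fisher enrichment p.

    The p-value is the hypergeometric tail P(X >= observed overlap) for
    drawing |B| events from a universe containing |A| marked events.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValueError(f"universe_size {universe_size} smaller than |A ∪ B| = {union}")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(set_a), len(set_b)))
    return k, min(1.0, p)
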