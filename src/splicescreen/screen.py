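"""Barcode-enrichment scoring for a pooled ORF overexpression screen.

A pooled screen tags every open reading frame (ORF) with a unique DNA
barcode.  Cells that acquire the phenotype of interest (here: the
CD44-high, mesenchymal-like state) are sorted out, and barcodes are
sequenced in the sorted pool and in the matched unsorted pool.  An ORF
that drives the phenotype is enriched in the sorted pool.

The scoring chain is deliberately simple and fully reproducible:

1. normalise every sample to one million barcode reads,
2. per barcode, log2 fold-change of sorted over unsorted (with a
   pseudocount for zero counts),
3. average the log fold-changes across biological replicates,
4. standardise across barcodes to Z scores,
5. call hits at a strict ``Z > cutoff`` (default 3 standard deviations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeCountMatrix",
    "ScreenScores",
    "normalize_counts",
    "log2_fold_change",
    "zscore_standardize",
    "call_hits",
    "replicate_concordance",
    "run_screen_analysis",
]

ROLE_SORTED = "sorted"
ROLE_UNSORTED = "unsorted"


@dataclass
class BarcodeCountMatrix:
    """Integer barcode counts per sample plus the sample pairing sheet.

    Parameters
    ----------
    counts
        Barcode x sample table of non-negative integer read counts,
        indexed by unique barcode id.
    orf_ids
        Barcode -> ORF mapping (several barcodes may tag one ORF).
    samples
        One row per sample with columns ``role`` (``sorted`` or
        ``unsorted``), ``replicate`` (int) and ``pair`` (for a sorted
        sample, the name of its unsorted reference; empty otherwise).
    """

    counts: pd.DataFrame
    orf_ids: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("barcode ids must be unique")
        if not self.counts.index.equals(self.orf_ids.index):
            self.orf_ids = self.orf_ids.reindex(self.counts.index)
            if self.orf_ids.isna().any():
                raise ValueError("every barcode needs an orf_id")
        missing = set(self.samples.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"sample sheet rows without count columns: {sorted(missing)}")
        bad_roles = set(self.samples["role"]) - {ROLE_SORTED, ROLE_UNSORTED}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        for name, row in self.samples.iterrows():
            if row["role"] == ROLE_SORTED:
                if row["pair"] not in self.samples.index:
                    raise ValueError(f"sorted sample {name!r} has no unsorted pair")
                if self.samples.loc[row["pair"], "role"] != ROLE_UNSORTED:
                    raise ValueError(f"pair of {name!r} is not an unsorted sample")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample must have a positive total count")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sorted_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["role"] == ROLE_SORTED]

    def pairs(self) -> list[tuple[str, str, int]]:
        """(sorted sample, unsorted sample, replicate) triples, by replicate."""
        rows = self.sorted_samples.sort_values("replicate")
        return [(s, r["pair"], int(r["replicate"])) for s, r in rows.iterrows()]


@dataclass
class ScreenScores:
    """Per-barcode screen result table plus an ORF-level aggregation.

    ``table`` has one row per barcode: per-replicate log2 fold-changes,
    their mean, the across-barcode Z score and the hit flag.
    ``orf_scores`` aggregates to ORF level by the maximum Z across the
    ORF's barcodes (degenerate when barcodes map 1:1 to ORFs).
    """

    table: pd.DataFrame
    cutoff: float
    orf_scores: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.orf_scores is None:
            agg = self.table.groupby("orf_id")["z"].max().to_frame("z")
            agg["hit"] = agg["z"] > self.cutoff
            self.orf_scores = agg.sort_values("z", ascending=False)

    @property
    def hits(self) -> list[str]:
        """Barcode ids with Z above the cutoff, highest Z first."""
        return call_hits(self.table["z"], self.cutoff)


def normalize_counts(counts: pd.DataFrame | np.ndarray, scale: float = 1e6):
    """Scale each sample (column) to a fixed total of ``scale`` reads.

    Proportions within a sample are preserved; an all-zero column is an
    error because it carries no information to renormalise.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    totals = arr.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize a sample with zero total counts")
    norm = arr * (scale / totals)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(norm, index=counts.index, columns=counts.columns)
    if isinstance(counts, pd.Series):
        return pd.Series(norm[:, 0], index=counts.index)
    return norm if np.asarray(counts).ndim > 1 else norm[:, 0]


def log2_fold_change(sorted_norm, unsorted_norm, pseudocount: float = 1.0):
    """log2(sorted + pc) - log2(unsorted + pc), elementwise.

    ``pseudocount`` must be positive if either input contains zeros.
    """
    s = np.asarray(sorted_norm, dtype=float)
    u = np.asarray(unsorted_norm, dtype=float)
    if s.shape != u.shape:
        raise ValueError("sorted and unsorted vectors must be aligned")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (np.any(s == 0) or np.any(u == 0)):
        raise ValueError("zero counts present; use a positive pseudocount")
    lfc = np.log2(s + pseudocount) - np.log2(u + pseudocount)
    if isinstance(sorted_norm, pd.Series):
        return pd.Series(lfc, index=sorted_norm.index)
    return lfc


def zscore_standardize(values, ddof: int = 1):
    """Standardise to mean 0, SD 1 across barcodes.

    Uses the sample standard deviation (``ddof=1``) by default; the
    population flavour is available via ``ddof=0``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least two distinct values to standardize")
    sd = v.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant input has zero standard deviation")
    z = (v - v.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(z, index=values.index)
    return z


def call_hits(z: pd.Series, cutoff: float = 3.0) -> list[str]:
    """Ids with Z strictly greater than ``cutoff``, ordered by descending Z."""
    z = pd.Series(z)
    hits = z[z > cutoff].sort_values(ascending=False)
    return list(hits.index)


def replicate_concordance(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between replicate score vectors."""
    if per_replicate.shape[1] < 2:
        raise ValueError("need at least two replicates")
    if per_replicate.isna().any().any():
        raise ValueError("replicate vectors must be complete and aligned")
    return per_replicate.corr(method="pearson")


def run_screen_analysis(
    matrix: BarcodeCountMatrix,
    pseudocount: float = 1.0,
    cutoff: float = 3.0,
    combine: str = "mean_logfc_then_z",
    ddof: int = 1,
) -> ScreenScores:
    """Full screen scoring: normalise, log2 FC per replicate, combine, Z, hits.

    ``combine`` selects how replicates enter the Z score:

    - ``mean_logfc_then_z`` (default): average the replicate log
      fold-changes per barcode, then standardise once across barcodes.
    - ``z_per_replicate_then_mean``: standardise each replicate's log
      fold-changes separately and average the Z scores (the reported
      ``z`` then has SD below 1 by construction).
    """
    if combine not in ("mean_logfc_then_z", "z_per_replicate_then_mean"):
        raise ValueError(f"unknown combine mode {combine!r}")
    norm = normalize_counts(matrix.counts)
    lfc = {}
    for sorted_s, unsorted_s, rep in matrix.pairs():
        lfc[f"logfc_rep{rep}"] = log2_fold_change(
            norm[sorted_s], norm[unsorted_s], pseudocount
        )
    lfc_df = pd.DataFrame(lfc, index=matrix.counts.index)
    mean_lfc = lfc_df.mean(axis=1)
    if combine == "mean_logfc_then_z":
        z = zscore_standardize(mean_lfc, ddof=ddof)
    else:
        z = lfc_df.apply(lambda col: zscore_standardize(col, ddof=ddof)).mean(axis=1)
    table = lfc_df.copy()
    table.insert(0, "orf_id", matrix.orf_ids)
    table["mean_logfc"] = mean_lfc
    table["z"] = z
    table["hit"] = z > cutoff
    table.index.name = "barcode_id"
    return ScreenScores(table=table, cutoff=cutoff)
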