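"""Readers and writers for the pipeline's plain-text formats.

TSV for count and expression matrices, GMT for gene sets, an
rMATS-style skipped-exon table for splice events, BED6+2 for peaks
(columns 7-8 hold the peak p-value and fold enrichment), a two-column
chromosome-length table, and JSON for simulation ground truth.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, PeakSet
from .screen import BarcodeCountMatrix
from .signature import GeneSet
from .splicing import JunctionCounts, SpliceEvent

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_rmats_se",
    "write_rmats_se",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_barcode_counts",
    "write_barcode_counts",
    "read_expression",
    "write_expression",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

RMATS_COLUMNS = [
    "ID", "GeneID", "chr", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen",
]


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, name TAB description TAB members."""
    sets = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                    "name, description and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            direction = "UP" if name.endswith("_UP") else "DOWN" if name.endswith("_DOWN") else "NA"
            sets.append(GeneSet(name, tuple(members), direction, description))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, gs.description or "na", *gs.members]) + "\n")


def _split_counts(cell: str, column: str, lineno: int) -> list[int]:
    try:
        return [int(v) for v in str(cell).split(",")]
    except ValueError as exc:
        raise ValueError(f"non-integer count in {column} at line {lineno}: {cell!r}") from exc


def read_rmats_se(path) -> tuple[list[SpliceEvent], JunctionCounts]:
    """Read an rMATS-style SE table into events and per-replicate counts.

    Replicate counts are comma-separated within the IJC/SJC columns;
    sample 1 replicates become group1, sample 2 replicates group2.
    Coordinates stay 0-based half-open.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RMATS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing rMATS columns {missing}")
    events, inc_rows, skip_rows, ids = [], [], [], []
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        event = SpliceEvent(
            event_id=str(row.ID),
            gene=str(row.GeneID),
            etype="SE",
            chrom=str(getattr(row, "chr")),
            strand=str(row.strand),
            exon_start=int(row.exonStart_0base),
            exon_end=int(row.exonEnd),
            upstream_exon=(int(row.upstreamES), int(row.upstreamEE)),
            downstream_exon=(int(row.downstreamES), int(row.downstreamEE)),
            l_inc=int(row.IncFormLen),
            l_skip=int(row.SkipFormLen),
        )
        ic1 = _split_counts(row.IJC_SAMPLE_1, "IJC_SAMPLE_1", lineno)
        sc1 = _split_counts(row.SJC_SAMPLE_1, "SJC_SAMPLE_1", lineno)
        ic2 = _split_counts(row.IJC_SAMPLE_2, "IJC_SAMPLE_2", lineno)
        sc2 = _split_counts(row.SJC_SAMPLE_2, "SJC_SAMPLE_2", lineno)
        if len(ic1) != len(sc1) or len(ic2) != len(sc2):
            raise ValueError(f"{path}: replicate count mismatch at line {lineno}")
        events.append(event)
        ids.append(event.event_id)
        inc_rows.append(ic1 + ic2)
        skip_rows.append(sc1 + sc2)
    if not events:
        raise ValueError(f"{path}: no events found")
    n1 = len(inc_rows[0]) - len(_split_counts(table.iloc[0]["IJC_SAMPLE_2"], "IJC_SAMPLE_2", 2))
    n2 = len(inc_rows[0]) - n1
    samples = [f"g1_rep{r}" for r in range(1, n1 + 1)] + [
        f"g2_rep{r}" for r in range(1, n2 + 1)
    ]
    index = pd.Index(ids, name="event_id")
    counts = JunctionCounts(
        inclusion=pd.DataFrame(inc_rows, index=index, columns=samples),
        skipping=pd.DataFrame(skip_rows, index=index, columns=samples),
        groups={s: ("group1" if s.startswith("g1") else "group2") for s in samples},
    )
    return events, counts


def write_rmats_se(events: list[SpliceEvent], counts: JunctionCounts, path) -> None:
    """Write events and counts back into the rMATS SE dialect."""
    g1 = counts.samples_in_group("group1")
    g2 = counts.samples_in_group("group2")
    rows = []
    for ev in events:
        rows.append(
            {
                "ID": ev.event_id,
                "GeneID": ev.gene,
                "chr": ev.chrom,
                "strand": ev.strand,
                "exonStart_0base": ev.exon_start,
                "exonEnd": ev.exon_end,
                "upstreamES": ev.upstream_exon[0],
                "upstreamEE": ev.upstream_exon[1],
                "downstreamES": ev.downstream_exon[0],
                "downstreamEE": ev.downstream_exon[1],
                "IJC_SAMPLE_1": ",".join(str(int(v)) for v in counts.inclusion.loc[ev.event_id, g1]),
                "SJC_SAMPLE_1": ",".join(str(int(v)) for v in counts.skipping.loc[ev.event_id, g1]),
                "IJC_SAMPLE_2": ",".join(str(int(v)) for v in counts.inclusion.loc[ev.event_id, g2]),
                "SJC_SAMPLE_2": ",".join(str(int(v)) for v in counts.skipping.loc[ev.event_id, g2]),
                "IncFormLen": ev.l_inc,
                "SkipFormLen": ev.l_skip,
            }
        )
    pd.DataFrame(rows, columns=RMATS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bed_peaks(path, label: str | None = None, genome: GenomeLayout | None = None) -> PeakSet:
    """Read BED6(+2) peaks; columns 7-8 are p-value and fold enrichment.

    Peaks without the two statistic columns default to (p=1, fold=0)
    with a warning, which the significance filter will then remove.
    """
    intervals = []
    warned = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno} has fewer than 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if start < 0 or start >= end:
                raise ValueError(f"{path}: invalid interval at line {lineno}: {start}-{end}")
            if len(fields) >= 8:
                p_value, fold = float(fields[6]), float(fields[7])
            else:
                p_value, fold = 1.0, 0.0
                if not warned:
                    logger.warning("%s: no statistic columns; defaulting to p=1, fold=0", path)
                    warned = True
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, strand=strand,
                                p_value=p_value, fold_enrichment=fold)
            )
    return PeakSet(label or Path(path).stem, intervals, genome=genome)


def write_bed_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as handle:
        for iv in peaks.intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}"
                f"\t{iv.p_value:.6g}\t{iv.fold_enrichment:.6g}\n"
            )


def read_chrom_sizes(path) -> GenomeLayout:
    lengths = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno} needs chrom and length")
            lengths[fields[0]] = int(fields[1])
    return GenomeLayout(lengths)


def write_chrom_sizes(genome: GenomeLayout, path) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(genome.lengths):
            handle.write(f"{chrom}\t{genome.lengths[chrom]}\n")


def read_barcode_counts(counts_path, sample_sheet_path) -> BarcodeCountMatrix:
    """Read a barcode counts TSV plus its sample sheet.

    Counts: ``barcode_id  orf_id  <one column per sample>``.
    Sample sheet: ``sample  role  replicate  pair``.
    """
    table = pd.read_csv(counts_path, sep="\t")
    if "barcode_id" not in table.columns or "orf_id" not in table.columns:
        raise ValueError(f"{counts_path}: needs barcode_id and orf_id columns")
    table = table.set_index("barcode_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"pair": str}).fillna({"pair": ""})
    for col in ("sample", "role", "replicate", "pair"):
        if col not in sheet.columns:
            raise ValueError(f"{sample_sheet_path}: missing column {col!r}")
    sheet = sheet.set_index("sample")
    sample_cols = [c for c in table.columns if c != "orf_id"]
    counts = table[sample_cols].astype(int)
    return BarcodeCountMatrix(counts=counts, orf_ids=table["orf_id"], samples=sheet)


def write_barcode_counts(matrix: BarcodeCountMatrix, counts_path, sample_sheet_path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "orf_id", matrix.orf_ids)
    out.to_csv(counts_path, sep="\t")
    matrix.samples.to_csv(sample_sheet_path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return expr


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def write_truth(truth, path) -> None:
    with open(path, "w") as handle:
        json.dump(truth.to_dict(), handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")


def read_truth(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return {k: list(map(float, v)) for k, v in obj.iterrows()}
    raise TypeError(f"cannot serialise {type(obj)!r}")
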