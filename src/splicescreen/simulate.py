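"""Synthetic datasets with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes — multinomial barcode counts with enriched ORFs planted, binomial
junction counts given a true PSI, expression matrices with a planted
mesenchymal signature, bivariate Gaussian pairs of known correlation,
interval sets with planted co-occurrence, and a bimodal PSI across cell
lines — and returns both the dataset and a :class:`SimTruth` record of
what was planted.  All generators are pure functions of their arguments
including the seed, so every downstream result is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, PeakSet
from .screen import BarcodeCountMatrix
from .signature import GeneSet
from .splicing import JunctionCounts, SpliceEvent

__all__ = [
    "SimTruth",
    "simulate_screen",
    "simulate_junction_counts",
    "simulate_expression",
    "simulate_bivariate",
    "simulate_peaks",
    "simulate_bimodal_psi",
]


@dataclass
class SimTruth:
    """Ground truth planted by a generator (only the relevant fields set)."""

    planted_hits: set[str] = field(default_factory=set)
    true_psi: pd.DataFrame | None = None
    true_delta_events: set[str] = field(default_factory=set)
    sample_labels: dict[str, str] = field(default_factory=dict)
    true_rho: float | None = None
    cooccurring_pairs: set[tuple[int, int]] = field(default_factory=set)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["planted_hits"] = sorted(self.planted_hits)
        out["true_delta_events"] = sorted(self.true_delta_events)
        out["cooccurring_pairs"] = sorted(map(list, self.cooccurring_pairs))
        if self.true_psi is not None:
            out["true_psi"] = {
                eid: [float(v) for v in row] for eid, row in self.true_psi.iterrows()
            }
        return out


def simulate_screen(
    n_barcodes: int,
    n_hits: int,
    enrichment_fold: float,
    depth: float,
    n_replicates: int = 2,
    seed: int = 0,
    abundance_sigma: float = 1.0,
) -> tuple[BarcodeCountMatrix, SimTruth]:
    """Pooled barcode screen with ``n_hits`` ORFs enriched in the sorted pool.

    Library abundances are log-normal (sigma ``abundance_sigma``, a
    skewed representation typical of pooled libraries).  Unsorted counts
    are multinomial(depth, abundance); sorted counts use the same
    abundances with the planted hits multiplied by ``enrichment_fold``
    and renormalised.  Each replicate draws an independent sorted /
    unsorted pair.
    """
    if n_hits >= n_barcodes:
        raise ValueError("n_hits must be smaller than n_barcodes")
    if depth <= 0 or enrichment_fold <= 0:
        raise ValueError("depth and enrichment_fold must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    width = len(str(n_barcodes))
    barcodes = [f"BC{i:0{width}d}" for i in range(1, n_barcodes + 1)]
    orfs = [f"ORF{i:0{width}d}" for i in range(1, n_barcodes + 1)]
    abundance = rng.lognormal(0.0, abundance_sigma, n_barcodes)
    abundance /= abundance.sum()
    hit_idx = rng.choice(n_barcodes, n_hits, replace=False)
    sorted_abundance = abundance.copy()
    sorted_abundance[hit_idx] *= enrichment_fold
    sorted_abundance /= sorted_abundance.sum()
    depth = int(depth)
    columns, sheet = {}, []
    for rep in range(1, n_replicates + 1):
        unsorted_name, sorted_name = f"unsorted_rep{rep}", f"sorted_rep{rep}"
        columns[unsorted_name] = rng.multinomial(depth, abundance)
        columns[sorted_name] = rng.multinomial(depth, sorted_abundance)
        sheet.append((unsorted_name, "unsorted", rep, ""))
        sheet.append((sorted_name, "sorted", rep, unsorted_name))
    counts = pd.DataFrame(columns, index=pd.Index(barcodes, name="barcode_id"))
    samples = pd.DataFrame(
        sheet, columns=["sample", "role", "replicate", "pair"]
    ).set_index("sample")
    matrix = BarcodeCountMatrix(
        counts=counts,
        orf_ids=pd.Series(orfs, index=counts.index, name="orf_id"),
        samples=samples,
    )
    truth = SimTruth(planted_hits={barcodes[i] for i in hit_idx})
    return matrix, truth


def _negative_binomial(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """NB draws parameterised by mean and dispersion: var = m + d m^2."""
    if dispersion == 0:
        return rng.poisson(mean, size)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean), size)


def simulate_junction_counts(
    n_events: int,
    n_per_group: int,
    coverage_mean: float,
    coverage_dispersion: float,
    base_psi_dist: tuple[float, float] = (2.0, 2.0),
    n_delta_events: int = 0,
    delta_psi: float = 0.0,
    lengths: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> tuple[list[SpliceEvent], JunctionCounts, SimTruth]:
    """Skipped-exon junction counts for two groups with planted delta-PSI.

    True PSI per event is Beta(``base_psi_dist``); ``n_delta_events``
    random events have their group-2 PSI shifted by +/-``delta_psi``
    (random sign, clipped to [0, 1]).  Per event and sample, total reads
    T are negative binomial (mean ``coverage_mean``, dispersion
    ``coverage_dispersion``); the inclusion count is Binomial(T, f) with
    f = psi*lI / (psi*lI + (1 - psi)*lS), and skipping = T - inclusion.
    """
    if n_events < 1 or n_per_group < 1:
        raise ValueError("n_events and n_per_group must be positive")
    if n_delta_events > n_events:
        raise ValueError("cannot plant more delta events than events")
    if not (0 <= delta_psi <= 1):
        raise ValueError("delta_psi must be in [0, 1]")
    a, b = base_psi_dist
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    l_inc, l_skip = lengths
    if l_inc < 1 or l_skip < 1:
        raise ValueError("effective lengths must be >= 1")
    if coverage_mean <= 0 or coverage_dispersion < 0:
        raise ValueError("coverage parameters out of range")
    rng = np.random.default_rng(seed)
    width = len(str(n_events))
    event_ids = [f"EV{i:0{width}d}" for i in range(1, n_events + 1)]
    psi1 = rng.beta(a, b, n_events)
    delta_idx = rng.choice(n_events, n_delta_events, replace=False)
    signs = rng.choice([-1.0, 1.0], n_delta_events)
    psi2 = psi1.copy()
    psi2[delta_idx] = np.clip(psi1[delta_idx] + signs * delta_psi, 0.0, 1.0)

    # Synthetic but valid SE geometry, events tiled along one chromosome.
    events = []
    pitch = 10_000
    for i, eid in enumerate(event_ids):
        base = 1_000 + i * pitch
        events.append(
            SpliceEvent(
                event_id=eid,
                gene=f"GENE{i + 1:0{width}d}",
                etype="SE",
                chrom="chr1",
                strand="+",
                exon_start=base + 500,
                exon_end=base + 650,
                upstream_exon=(base, base + 200),
                downstream_exon=(base + 1_000, base + 1_200),
                l_inc=l_inc,
                l_skip=l_skip,
            )
        )

    samples = [f"g1_rep{r}" for r in range(1, n_per_group + 1)] + [
        f"g2_rep{r}" for r in range(1, n_per_group + 1)
    ]
    groups = {s: ("group1" if s.startswith("g1") else "group2") for s in samples}
    inc = np.empty((n_events, 2 * n_per_group), dtype=int)
    skip = np.empty_like(inc)
    for j, sample in enumerate(samples):
        psi = psi1 if groups[sample] == "group1" else psi2
        total = _negative_binomial(rng, coverage_mean, coverage_dispersion, n_events)
        frac = psi * l_inc / (psi * l_inc + (1.0 - psi) * l_skip)
        inc[:, j] = rng.binomial(total, frac)
        skip[:, j] = total - inc[:, j]
    index = pd.Index(event_ids, name="event_id")
    counts = JunctionCounts(
        inclusion=pd.DataFrame(inc, index=index, columns=samples),
        skipping=pd.DataFrame(skip, index=index, columns=samples),
        groups=groups,
    )
    truth = SimTruth(
        true_psi=pd.DataFrame(
            {"group1": psi1, "group2": psi2}, index=index
        ),
        true_delta_events={event_ids[i] for i in delta_idx},
    )
    return events, counts, truth


def simulate_expression(
    n_genes: int,
    n_samples: int,
    mesenchymal_fraction: float = 0.5,
    up_set_size: int = 50,
    down_set_size: int = 50,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSet, GeneSet, SimTruth]:
    """Expression matrix with a planted mesenchymal UP/DOWN signature.

    Baseline expression is Normal(0, noise_sd) per gene and sample;
    mesenchymal samples get ``+effect`` added on the UP-set genes and
    ``-effect`` on the (disjoint) DOWN-set genes.
    """
    if up_set_size + down_set_size >= n_genes:
        raise ValueError("gene sets must be smaller than the gene universe")
    if not 0 < mesenchymal_fraction < 1:
        raise ValueError("mesenchymal_fraction must be in (0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    expr = rng.normal(0.0, noise_sd, (n_genes, n_samples))
    gene_idx = rng.permutation(n_genes)
    up_idx = gene_idx[:up_set_size]
    down_idx = gene_idx[up_set_size:up_set_size + down_set_size]
    n_mes = max(1, int(round(mesenchymal_fraction * n_samples)))
    mes_idx = rng.choice(n_samples, n_mes, replace=False)
    expr[np.ix_(up_idx, mes_idx)] += effect
    expr[np.ix_(down_idx, mes_idx)] -= effect
    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    up = GeneSet("SIM_EMT_UP", tuple(genes[i] for i in sorted(up_idx)), "UP")
    down = GeneSet("SIM_EMT_DOWN", tuple(genes[i] for i in sorted(down_idx)), "DOWN")
    labels = {
        s: ("mesenchymal" if i in set(mes_idx) else "epithelial")
        for i, s in enumerate(samples)
    }
    return matrix, up, down, SimTruth(sample_labels=labels)


def simulate_bivariate(n: int, rho: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal draws with unit variances and correlation ``rho``."""
    if n < 8:
        raise ValueError("need n >= 8")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if abs(rho) == 1.0:
        return x, np.sign(rho) * x
    y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return x, y


def simulate_peaks(
    genome: GenomeLayout,
    n_a: int,
    n_b: int,
    length_mean: float = 200.0,
    cooccur_fraction: float = 0.0,
    jitter: int = 0,
    seed: int = 0,
) -> tuple[PeakSet, PeakSet, SimTruth]:
    """Two peak sets with a planted fraction of co-occurring B peaks.

    A peaks are uniform over the genome (chromosomes weighted by
    length).  ``cooccur_fraction`` of the B peaks are anchored at an A
    peak's start +/- uniform jitter (cycling through A peaks so the
    planted overlaps hit distinct A peaks whenever possible); the rest
    are uniform.  Peak statistics (p-value, fold enrichment) are drawn
    in the significant range so the sets pass the default peak filter.
    """
    if not 0.0 <= cooccur_fraction <= 1.0:
        raise ValueError("cooccur_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.lengths)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def draw_length() -> int:
        return max(1, int(rng.poisson(length_mean)))

    def uniform_peak(name: str) -> GenomicInterval:
        ci = int(rng.choice(len(chroms), p=weights))
        ln = min(draw_length(), genome.lengths[chroms[ci]])
        start = int(rng.integers(0, genome.lengths[chroms[ci]] - ln + 1))
        return GenomicInterval(
            chrom=chroms[ci], start=start, end=start + ln, name=name, strand="+",
            p_value=float(10.0 ** -rng.uniform(5, 10)),
            fold_enrichment=float(rng.uniform(8, 20)),
        )

    peaks_a = [uniform_peak(f"A{i:04d}") for i in range(n_a)]
    n_co = int(round(cooccur_fraction * n_b))
    peaks_b, pairs = [], set()
    for j in range(n_b):
        if j < n_co:
            anchor_idx = j % n_a
            anchor = peaks_a[anchor_idx]
            ln = min(draw_length(), genome.lengths[anchor.chrom])
            offset = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
            start = int(np.clip(anchor.start + offset, 0, genome.lengths[anchor.chrom] - ln))
            peaks_b.append(
                GenomicInterval(
                    chrom=anchor.chrom, start=start, end=start + ln,
                    name=f"B{j:04d}", strand="+",
                    p_value=float(10.0 ** -rng.uniform(5, 10)),
                    fold_enrichment=float(rng.uniform(8, 20)),
                )
            )
            pairs.add((anchor_idx, j))
        else:
            peaks_b.append(uniform_peak(f"B{j:04d}"))
    truth = SimTruth(cooccurring_pairs=pairs)
    return (
        PeakSet("A", peaks_a, genome=genome),
        PeakSet("B", peaks_b, genome=genome),
        truth,
    )


def simulate_bimodal_psi(
    n_lines: int,
    frac_low: float,
    low_mode: float,
    high_mode: float,
    sd: float,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Bimodal PSI across cell lines (e.g. FLNB exon 30 inclusion).

    ``frac_low`` of the lines draw near ``low_mode`` (exon mostly
    skipped, the mesenchymal-like pattern), the rest near ``high_mode``;
    draws are Normal(mode, sd) truncated to [0, 1].  Returns the PSI
    vector and the mode label ('low'/'high') per line.
    """
    if not 0 <= low_mode < high_mode <= 1:
        raise ValueError("need 0 <= low_mode < high_mode <= 1")
    if not 0 <= frac_low <= 1:
        raise ValueError("frac_low must be in [0, 1]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_low = int(round(frac_low * n_lines))
    modes = np.array([low_mode] * n_low + [high_mode] * (n_lines - n_low))
    order = rng.permutation(n_lines)
    modes = modes[order]
    psi = np.clip(modes + rng.normal(0.0, 1.0, n_lines) * sd, 0.0, 1.0)
    lines = pd.Index([f"LINE{i:03d}" for i in range(1, n_lines + 1)], name="cell_line")
    labels = pd.Series(np.where(modes == low_mode, "low", "high"), index=lines, name="mode")
    return pd.Series(psi, index=lines, name="psi"), labels
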