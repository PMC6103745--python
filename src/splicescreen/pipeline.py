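"""End-to-end orchestration over synthetic data, with a validated config.

``run_all`` executes every stage — screen simulation and scoring,
junction-count simulation and differential splicing, expression
simulation with signature scoring and extreme-quantile classification,
information-coefficient association against a planted feature, and the
peak-overlap permutation test — and writes a machine-readable JSON
report plus a short human-readable summary.  Every random draw flows
through seeds derived from the single configured master seed, so a run
is byte-identical given the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .association import associate_features
from .intervals import GenomeLayout, filter_peaks, overlap_permutation_test
from .screen import run_screen_analysis
from .signature import classify_extremes, combined_signature_score
from .splicing import differential_splicing, tally_event_types

__all__ = ["PipelineConfig", "run_all", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ScreenConfig:
    n_barcodes: int = 2000
    n_hits: int = 15
    enrichment_fold: float = 8.0
    depth: float = 400_000
    n_replicates: int = 2
    pseudocount: float = 1.0
    cutoff: float = 3.0

    def validate(self) -> None:
        if self.n_hits >= self.n_barcodes:
            raise ConfigError("screen: n_hits must be < n_barcodes")
        if self.depth <= 0 or self.enrichment_fold <= 0 or self.pseudocount < 0:
            raise ConfigError("screen: depth/enrichment_fold/pseudocount out of range")


@dataclass
class SplicingConfig:
    n_events: int = 300
    n_per_group: int = 3
    coverage_mean: float = 100.0
    coverage_dispersion: float = 0.3
    n_delta_events: int = 30
    delta_psi: float = 0.4
    min_total: int = 10
    min_abs_dpsi: float = 0.05
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("splicing: alpha must be in (0, 1)")
        if not 0 <= self.delta_psi <= 1:
            raise ConfigError("splicing: delta_psi must be in [0, 1]")
        if self.n_delta_events > self.n_events:
            raise ConfigError("splicing: more delta events than events")


@dataclass
class SignatureConfig:
    n_genes: int = 2000
    n_samples: int = 120
    mesenchymal_fraction: float = 0.4
    up_set_size: int = 50
    down_set_size: int = 50
    effect: float = 3.0
    noise_sd: float = 1.0
    ssgsea_alpha: float = 0.25
    fraction: float = 0.2

    def validate(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ConfigError("signature: fraction must be in (0, 0.5]")
        if self.up_set_size + self.down_set_size >= self.n_genes:
            raise ConfigError("signature: gene sets larger than universe")


@dataclass
class AssociationConfig:
    n_samples: int = 60
    rho: float = 0.85
    n_noise_features: int = 20
    n_perm: int = 199

    def validate(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ConfigError("association: |rho| must be <= 1")
        if self.n_perm < 99:
            raise ConfigError("association: n_perm must be >= 99")


@dataclass
class OverlapConfig:
    chrom_length: int = 1_000_000
    n_chroms: int = 2
    n_peaks: int = 200
    length_mean: float = 200.0
    cooccur_fraction: float = 0.5
    n_perm: int = 199

    def validate(self) -> None:
        if not 0 <= self.cooccur_fraction <= 1:
            raise ConfigError("overlap: cooccur_fraction must be in [0, 1]")
        if self.n_perm < 99:
            raise ConfigError("overlap: n_perm must be >= 99")


@dataclass
class PipelineConfig:
    """Validated per-stage parameters plus the master seed."""

    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    splicing: SplicingConfig = field(default_factory=SplicingConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ConfigError("seed must be an integer")
        for stage in (self.screen, self.splicing, self.signature, self.association, self.overlap):
            stage.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        stages = {
            "screen": ScreenConfig,
            "splicing": SplicingConfig,
            "signature": SignatureConfig,
            "association": AssociationConfig,
            "overlap": OverlapConfig,
        }
        kwargs: dict = {}
        for name, stage_cls in stages.items():
            if name in data:
                kwargs[name] = _build(stage_cls, data.pop(name) or {}, name)
        if "seed" in data:
            kwargs["seed"] = data.pop("seed")
        if data:
            raise ConfigError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage on synthetic data and return the report dict.

    When ``out_dir`` is given, writes ``report.json`` (sorted keys, so
    byte-identical across runs with the same config) and ``summary.txt``.
    """
    seeds = _stage_seeds(config.seed, 6)
    report: dict = {"config": config.to_dict()}

    # --- screen: simulate, score, compare with planted truth ---
    sc = config.screen
    matrix, truth = simulate.simulate_screen(
        sc.n_barcodes, sc.n_hits, sc.enrichment_fold, sc.depth, sc.n_replicates, seed=seeds[0]
    )
    scores = run_screen_analysis(matrix, pseudocount=sc.pseudocount, cutoff=sc.cutoff)
    called = set(scores.hits)
    tp = len(called & truth.planted_hits)
    report["screen"] = {
        "n_called": len(called),
        "n_planted": sc.n_hits,
        "sensitivity": tp / sc.n_hits,
        "false_discovery_rate": 1.0 - tp / len(called) if called else 0.0,
        "z_mean": float(scores.table["z"].mean()),
        "z_sd": float(scores.table["z"].std(ddof=1)),
    }
    logger.info("screen: %d barcodes in, %d hits called", sc.n_barcodes, len(called))

    # --- splicing: simulate junction counts, call differential events ---
    sp = config.splicing
    events, counts, sp_truth = simulate.simulate_junction_counts(
        sp.n_events, sp.n_per_group, sp.coverage_mean, sp.coverage_dispersion,
        n_delta_events=sp.n_delta_events, delta_psi=sp.delta_psi, seed=seeds[1],
    )
    diff = differential_splicing(
        events, counts, "group1", "group2",
        min_total=sp.min_total, min_abs_dpsi=sp.min_abs_dpsi, alpha=sp.alpha,
    )
    sig = set(diff.index[diff["significant"]])
    tp = len(sig & sp_truth.true_delta_events)
    tally = tally_event_types(diff)
    report["splicing"] = {
        "n_events_tested": int(len(diff)),
        "n_significant": len(sig),
        "sensitivity": tp / max(1, len(sp_truth.true_delta_events)),
        "false_discovery_rate": 1.0 - tp / len(sig) if sig else 0.0,
        "tally": {et: {d: int(tally.loc[et, d]) for d in tally.columns} for et in tally.index},
    }
    logger.info("splicing: %d/%d events pass the count filter, %d significant",
                len(diff), sp.n_events, len(sig))

    # --- signature: simulate expression, score, classify extremes ---
    sg = config.signature
    expr, up, down, sg_truth = simulate.simulate_expression(
        sg.n_genes, sg.n_samples, sg.mesenchymal_fraction,
        sg.up_set_size, sg.down_set_size, sg.effect, sg.noise_sd, seed=seeds[2],
    )
    combined = combined_signature_score(expr, up, down, alpha=sg.ssgsea_alpha)
    labels = classify_extremes(combined, fraction=sg.fraction)
    truth_labels = pd.Series(sg_truth.sample_labels)
    called_extreme = labels[labels != "intermediate"]
    agreement = float((truth_labels[called_extreme.index] == called_extreme).mean())
    mes = truth_labels == "mesenchymal"
    sep = (combined[mes].mean() - combined[~mes].mean()) / combined[~mes].std(ddof=1)
    report["signature"] = {
        "n_labeled_per_tail": int((labels == "mesenchymal").sum()),
        "extreme_label_agreement": agreement,
        "group_separation_sd": float(sep),
    }

    # --- association: planted feature among noise features ---
    ac = config.association
    x, y = simulate.simulate_bivariate(ac.n_samples, ac.rho, seed=seeds[3])
    sample_ids = [f"S{i:03d}" for i in range(ac.n_samples)]
    profile = pd.Series(x, index=sample_ids, name="profile")
    rng = np.random.default_rng(seeds[4])
    features = pd.DataFrame(
        rng.standard_normal((ac.n_noise_features, ac.n_samples)),
        index=[f"noise_{i:02d}" for i in range(ac.n_noise_features)],
        columns=sample_ids,
    )
    features.loc["planted"] = y
    assoc = associate_features(profile, features, n_perm=ac.n_perm, seed=seeds[4])
    report["association"] = {
        "top_feature": str(assoc.index[0]),
        "planted_ic": float(assoc.loc["planted", "ic"]),
        "planted_p": float(assoc.loc["planted", "p"]),
        "planted_fdr": float(assoc.loc["planted", "fdr"]),
        "planted_rank": int(assoc.index.get_loc("planted")) + 1,
    }

    # --- interval overlap: planted co-occurrence, permutation test ---
    ov = config.overlap
    genome = GenomeLayout({f"chr{i+1}": ov.chrom_length for i in range(ov.n_chroms)})
    peaks_a, peaks_b, _ = simulate.simulate_peaks(
        genome, ov.n_peaks, ov.n_peaks, ov.length_mean,
        cooccur_fraction=ov.cooccur_fraction, seed=seeds[5],
    )
    peaks_a, peaks_b = filter_peaks(peaks_a), filter_peaks(peaks_b)
    perm = overlap_permutation_test(peaks_a, peaks_b, genome, n_perm=ov.n_perm, seed=seeds[5])
    report["overlap"] = {
        "observed": int(perm["observed"]),
        "null_mean": perm["null_mean"],
        "p": perm["p"],
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
        (out / "summary.txt").write_text(_summary(report))
    return report


def _summary(report: dict) -> str:
    lines = [
        "splicescreen end-to-end synthetic run",
        f"  screen:    {report['screen']['n_called']} hits called, "
        f"sensitivity {report['screen']['sensitivity']:.2f}, "
        f"FDR {report['screen']['false_discovery_rate']:.2f}",
        f"  splicing:  {report['splicing']['n_significant']} significant events, "
        f"sensitivity {report['splicing']['sensitivity']:.2f}, "
        f"FDR {report['splicing']['false_discovery_rate']:.2f}",
        f"  signature: extreme-label agreement {report['signature']['extreme_label_agreement']:.2f}, "
        f"separation {report['signature']['group_separation_sd']:.1f} SD",
        f"  assoc:     planted feature rank {report['association']['planted_rank']}, "
        f"IC {report['association']['planted_ic']:.3f}, p {report['association']['planted_p']:.4g}",
        f"  overlap:   observed {report['overlap']['observed']} vs null mean "
        f"{report['overlap']['null_mean']:.1f}, p {report['overlap']['p']:.4g}",
    ]
    return "\n".join(lines) + "\n"
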