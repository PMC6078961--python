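"""End-to-end orchestration: design -> mixtures -> simulation -> QC report.

The QC report is a plain dict (JSON-serializable) with a rendered text
summary; every number in the text render is present in the JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import DesignConfig, design_sequins
from .diffnorm import diff_test, roc_curve
from .ladder import (
    bias_profile,
    coverage_summary,
    detection_limits,
    fit_ladder,
)
from .mixtures import build_ladder, build_mix_pair, expected_lfc
from .simulate import ErrorModel, compose_sample, generate_fixture_genomes, simulate_short_reads

logger = logging.getLogger("metaquin")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 7
    n_genomes: int = 10
    genome_length: tuple[int, int] = (20000, 60000)
    gc_range: tuple[float, float] = (0.20, 0.71)
    n_points: int = 16
    dilution: float = 2.0
    anchor: float = 60.0
    n_fold_change: int = 50
    lfc_magnitudes: tuple[int, ...] = (1, 2, 3)
    n_pairs: int = 100000
    replicates: int = 3
    alpha: float = 0.05
    design: DesignConfig = field(default_factory=DesignConfig)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _poisson_counts(mix, sequins, n_pairs, rng) -> pd.Series:
    mass = {e.sequin_id: e.concentration * e.length for e in mix.entries}
    total = sum(mass.values())
    lam = {k: 2 * n_pairs * v / total for k, v in mass.items()}
    ids = sorted(lam)
    return pd.Series(
        rng.poisson([lam[i] for i in ids]).astype(float), index=ids
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run design, mixture formulation, ladder simulation/QC and the
    Mix A/B differential check; returns the QC report dict."""
    report: dict = {"config": config.to_dict()}
    rng = np.random.default_rng(config.seed)

    logger.info("stage design: %d fixture genomes", config.n_genomes)
    genomes = generate_fixture_genomes(
        config.n_genomes, config.genome_length, config.gc_range,
        seed=int(rng.integers(2**31)),
    )
    design = design_sequins(genomes, config.design, rng_seed=int(rng.integers(2**31)))
    report["design"] = {
        "n_sequins": len(design.sequins),
        "failures": design.failures,
        "total_bp": sum(s.length for s in design.sequins),
    }
    logger.info("stage design: %d sequins", len(design.sequins))

    n_points = min(config.n_points, len(design.sequins))
    mix_a = build_ladder(design.sequins, n_points, config.dilution, config.anchor)
    n_fc = min(config.n_fold_change, 2 * (len(mix_a) // 2) - 2)
    n_fc -= n_fc % 2
    pair = build_mix_pair(mix_a, n_fc, config.lfc_magnitudes,
                          rng_seed=int(rng.integers(2**31)))
    report["mixtures"] = {
        "n_points": n_points,
        "dilution": config.dilution,
        "anchor_amol_per_ul": config.anchor,
        "n_fold_change": pair.n_fold_change,
        "n_equimolar": pair.n_equimolar,
        "dynamic_range_designed": config.dilution ** (n_points - 1),
    }

    logger.info("stage simulate: %d read pairs", config.n_pairs)
    lengths = {s.id: s.length for s in design.sequins}
    spec = compose_sample([], mixture=mix_a, sequin_lengths=lengths)
    reads = simulate_short_reads(
        spec, config.n_pairs, ErrorModel.error_free(),
        seed=int(rng.integers(2**31)), emit="placements_only",
    )
    cov = coverage_summary(reads.placements, {s.id: s.length for s in design.sequins})
    fit = fit_ladder(cov, mix_a)
    det = detection_limits(cov, mix_a)
    bias = bias_profile(cov, mix_a, "gc")
    report["ladder"] = {
        "slope": fit.slope,
        "slope_se": fit.slope_se,
        "r_squared": fit.r_squared,
        "n_used": fit.n_used,
        "excluded": list(fit.excluded),
        "n_detected": det.n_detected,
        "lod_amol_per_ul": det.lod,
        "dynamic_range": det.dynamic_range,
        "gc_bias_range": [
            float(bias.table["obs_over_exp"].min()),
            float(bias.table["obs_over_exp"].max()),
        ],
    }
    logger.info("stage qc: slope=%.3f R2=%.4f", fit.slope, fit.r_squared)

    logger.info("stage diffabund: %d vs %d replicates", config.replicates,
                config.replicates)
    cols = {}
    for r in range(config.replicates):
        cols[f"A{r + 1}"] = _poisson_counts(pair.mix_a, design.sequins,
                                            config.n_pairs, rng)
        cols[f"B{r + 1}"] = _poisson_counts(pair.mix_b, design.sequins,
                                            config.n_pairs, rng)
    counts = pd.DataFrame(cols)
    res = diff_test(
        counts,
        [f"A{r + 1}" for r in range(config.replicates)],
        [f"B{r + 1}" for r in range(config.replicates)],
        roles=pair.roles,
        alpha=config.alpha,
    )
    exp = expected_lfc(pair).set_index("sequin_id")
    merged = res.table.join(exp[["expected_lfc"]])
    ok = merged["observed_lfc"].notna() & merged["expected_lfc"].notna()
    r2 = float(
        np.corrcoef(merged.loc[ok, "observed_lfc"], merged.loc[ok, "expected_lfc"])[0, 1]
        ** 2
    )
    roc = roc_curve(
        res.table["p"].to_numpy(),
        (res.table["role"] == "fold_change").to_numpy(),
    )
    report["diffabund"] = {
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "lfc_r_squared": r2,
        "auc": roc.auc,
        "alpha": config.alpha,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "qc_report.json").write_text(render_json(report))
        (out / "qc_report.txt").write_text(render_text(report))
    return report


def render_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"


def render_text(report: dict) -> str:
    """Human-readable summary; every number also appears in the JSON."""
    lines = ["metaquin QC report", "=================="]
    d = report.get("design", {})
    if d:
        lines.append(f"sequins designed : {d['n_sequins']} ({d['total_bp']} bp)")
    m = report.get("mixtures", {})
    if m:
        lines.append(
            f"ladder           : {m['n_points']} points, dilution {m['dilution']}, "
            f"designed range {m['dynamic_range_designed']}"
        )
        lines.append(
            f"mix pair         : {m['n_fold_change']} fold-change / "
            f"{m['n_equimolar']} equimolar"
        )
    q = report.get("ladder", {})
    if q:
        lines.append(
            f"ladder fit       : slope {q['slope']:.4g} (SE {q['slope_se']:.2g}), "
            f"R^2 {q['r_squared']:.4g} on {q['n_used']} sequins"
        )
        lines.append(
            f"detection        : {q['n_detected']} detected, "
            f"LoD {q['lod_amol_per_ul']}, dynamic range {q['dynamic_range']}"
        )
    f = report.get("diffabund", {})
    if f:
        lines.append(
            f"differential     : sensitivity {f['sensitivity']:.4g}, "
            f"specificity {f['specificity']:.4g}, LFC R^2 "
            f"{f['lfc_r_squared']:.4g}, AUC {f['auc']:.4g}"
        )
    return "\n".join(lines) + "\n"
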