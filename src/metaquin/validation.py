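"""Reference validation experiments run entirely in silico.

Each function builds its own inputs (fixture genomes, designed sequins,
default mixtures), runs one of the package's headline experiments at the
default study conditions, and returns the summary statistics:

* :func:`ladder_quantification` -- neat Mix A library; ladder regression of
  log2 fold-coverage on log2 concentration.
* :func:`mix_pair_experiment` -- Mix A vs Mix B, three replicate libraries
  each; observed-vs-expected LFC agreement and the control-based
  sensitivity/specificity of the differential test.
* :func:`load_normalization_experiment` -- the six-mixture absolute-load
  layout (four community species, totals doubling, fixed spike); LFC
  recovery with and without sequin-fraction normalization.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignReport, design_sequins
from .diffnorm import (
    diff_test,
    normalize_absolute,
    normalize_conventional,
    observed_lfc,
    sequin_read_fraction,
)
from .ladder import coverage_summary, fit_ladder
from .mixtures import MixPairSpec, MixtureSpec, build_ladder, build_mix_pair, expected_lfc
from .simulate import (
    ErrorModel,
    compose_sample,
    generate_fixture_genomes,
    simulate_counts,
    simulate_short_reads,
)

N_SEQUINS = 86
MIN_LOW_POINT_COVERAGE = 1.2  # fold-coverage target at the lowest ladder point
MIN_LOW_POINT_READS = 50  # per-replicate read floor for the Mix A/B test


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


@dataclass
class DefaultDesign:
    genomes: dict[str, str]
    design: DesignReport
    mix_a: MixtureSpec
    pair: MixPairSpec

    @property
    def lengths(self) -> dict[str, int]:
        return {s.id: s.length for s in self.design.sequins}


def default_design(seed: int = 0, n_genomes: int = N_SEQUINS) -> DefaultDesign:
    """Design the default sequin set and mixtures from fixture genomes."""
    rng = np.random.default_rng(seed)
    genomes = generate_fixture_genomes(n_genomes, seed=_subseed(rng))
    design = design_sequins(genomes, rng_seed=_subseed(rng))
    mix_a = build_ladder(design.sequins)
    pair = build_mix_pair(mix_a, rng_seed=_subseed(rng))
    return DefaultDesign(genomes=genomes, design=design, mix_a=mix_a, pair=pair)


def ladder_pairs_for_coverage(
    mix: MixtureSpec, target: float = MIN_LOW_POINT_COVERAGE, read_bases: int = 250
) -> int:
    """Read pairs needed for the lowest ladder point to expect `target` x coverage."""
    total_mass = sum(e.concentration * e.length for e in mix.entries)
    lowest_conc = min(e.concentration for e in mix.entries)
    return int(math.ceil(target * total_mass / (read_bases * lowest_conc)))


def ladder_quantification(
    seed: int = 0, design: DefaultDesign | None = None
) -> dict:
    """Simulate a neat Mix A library and regress coverage on concentration.

    Error-free read-pair placements at a depth that gives the lowest ladder
    point an expected fold-coverage of at least 1x; returns the OLS slope,
    its standard error, R^2 and the simulated pair count.
    """
    rng = np.random.default_rng(seed)
    d = design or default_design(_subseed(rng))
    n_pairs = ladder_pairs_for_coverage(d.mix_a)
    spec = compose_sample([], mixture=d.mix_a, sequin_lengths=d.lengths)
    reads = simulate_short_reads(
        spec, n_pairs, ErrorModel.error_free(), seed=_subseed(rng),
        emit="placements_only",
    )
    cov = coverage_summary(reads.placements, d.lengths)
    fit = fit_ladder(cov, d.mix_a)
    return {
        "slope": fit.slope,
        "slope_se": fit.slope_se,
        "r_squared": fit.r_squared,
        "n_pairs": n_pairs,
        "n_used": fit.n_used,
    }


def mix_pair_reads_per_library(
    mix: MixtureSpec, floor: int = MIN_LOW_POINT_READS
) -> int:
    """Reads per library so the lowest-mass sequin expects >= `floor` reads."""
    total_mass = sum(e.concentration * e.length for e in mix.entries)
    min_mass = min(e.concentration * e.length for e in mix.entries)
    return int(math.ceil(floor * total_mass / min_mass))


def mix_pair_experiment(
    seed: int = 0,
    design: DefaultDesign | None = None,
    replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Mix A vs Mix B with Poisson count noise, 3 replicates each.

    Library depth is set so every sequin expects at least 50 reads per
    replicate (high depth across the whole ladder).  Returns the observed vs
    expected LFC regression R^2 and slope, plus the sensitivity and
    specificity of the Welch/BH differential test against the designed
    control roles.
    """
    rng = np.random.default_rng(seed)
    d = design or default_design(_subseed(rng))
    n_reads = mix_pair_reads_per_library(d.mix_a)
    cols: dict[str, pd.Series] = {}
    group_a, group_b = [], []
    for r in range(replicates):
        for label, mix in (("A", d.mix_a), ("B", d.pair.mix_b)):
            spec = compose_sample([], mixture=mix, sequin_lengths=d.lengths)
            name = f"{label}{r + 1}"
            cols[name] = simulate_counts(spec, n_reads, seed=_subseed(rng))
            (group_a if label == "A" else group_b).append(name)
    counts = pd.DataFrame(cols)
    res = diff_test(counts, group_a, group_b, roles=d.pair.roles, alpha=alpha)
    exp = expected_lfc(d.pair).set_index("sequin_id")[["expected_lfc"]]
    obs = observed_lfc(counts, group_a, group_b)
    merged = obs.join(exp)
    ok = merged["observed_lfc"].notna()
    lr = stats.linregress(
        merged.loc[ok, "expected_lfc"], merged.loc[ok, "observed_lfc"]
    )
    return {
        "lfc_r_squared": float(lr.rvalue**2),
        "lfc_slope": float(lr.slope),
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "n_reads_per_library": n_reads,
        "n_fold_change": d.pair.n_fold_change,
        "n_equimolar": d.pair.n_equimolar,
    }


# Fig.-4-style load experiment: community mass fractions per mixture and the
# doubling total loads.  The spike is a fixed mass (same volume of the sequin
# mixture into every sample).
COMPOSITION_A = (0.40, 0.30, 0.20, 0.10)
COMPOSITION_B = (0.10, 0.20, 0.30, 0.40)
TOTALS = {"A1": 1.0, "A2": 2.0, "A3": 4.0, "B1": 1.0, "B2": 2.0, "B3": 4.0}


def load_normalization_experiment(
    seed: int = 0,
    design: DefaultDesign | None = None,
    n_reads: int = 1_000_000,
    spike_mass_fraction: float = 0.05,
) -> dict:
    """Six mixtures of four species with doubling totals and a fixed spike.

    Simulates Poisson counts per library, computes conventional fractional
    abundances (genome size + library depth) and the absolute index obtained
    by dividing by the per-sample sequin read fraction, then regresses
    observed on expected LFC over all species x sample-pair comparisons for
    both normalizations.
    """
    rng = np.random.default_rng(seed)
    d = design or default_design(_subseed(rng))
    species_rng = np.random.default_rng(_subseed(rng))
    species = generate_fixture_genomes(
        4, (90_000, 110_000), seed=int(species_rng.integers(2**31))
    )
    names = sorted(species)
    sizes = {n: len(s) for n, s in species.items()}
    spike_mass = spike_mass_fraction * min(TOTALS.values())

    fractions = {}
    for sample in TOTALS:
        comp = COMPOSITION_A if sample.startswith("A") else COMPOSITION_B
        fractions[sample] = dict(zip(names, comp))

    cols = {}
    for sample, total in TOTALS.items():
        members = [
            (n, sizes[n], total * fractions[sample][n]) for n in names
        ]
        spec = compose_sample(
            members,
            mixture=d.mix_a,
            spike_mode=("fixed", spike_mass),
            sequin_lengths=d.lengths,
        )
        cols[sample] = simulate_counts(spec, n_reads, seed=_subseed(rng))
    counts = pd.DataFrame(cols)

    sequin_ids = [s.id for s in d.design.sequins]
    genome_sizes = {**sizes, **d.lengths}
    fractional = normalize_conventional(counts, genome_sizes, community_ids=names)
    phi = sequin_read_fraction(counts, sequin_ids)
    absolute = normalize_absolute(fractional, phi)

    samples = sorted(TOTALS)
    rows = []
    for sp in names:
        for s1, s2 in itertools.combinations(samples, 2):
            expected = math.log2(
                (TOTALS[s2] * fractions[s2][sp]) / (TOTALS[s1] * fractions[s1][sp])
            )
            rows.append(
                {
                    "species": sp,
                    "pair": f"{s1}/{s2}",
                    "expected_lfc": expected,
                    "lfc_absolute": math.log2(
                        absolute.loc[sp, s2] / absolute.loc[sp, s1]
                    ),
                    "lfc_conventional": math.log2(
                        fractional.loc[sp, s2] / fractional.loc[sp, s1]
                    ),
                }
            )
    table = pd.DataFrame(rows)
    fit_abs = stats.linregress(table["expected_lfc"], table["lfc_absolute"])
    fit_conv = stats.linregress(table["expected_lfc"], table["lfc_conventional"])
    return {
        "n_comparisons": len(table),
        "r_squared_absolute": float(fit_abs.rvalue**2),
        "r_squared_conventional": float(fit_conv.rvalue**2),
        "slope_absolute": float(fit_abs.slope),
        "phi": phi.to_dict(),
        "table": table,
    }
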