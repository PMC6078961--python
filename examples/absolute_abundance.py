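"""Absolute abundance via a fixed sequin spike.

Six mock communities of four species where total DNA doubles A1->A2->A3
(and B1->B2->B3) receive the same fixed amount of sequins. Conventional
fractional abundance cannot see the doubling (fractions are load-blind),
but dividing each fraction by the sequin read fraction phi rescales every
sample to the common spike reference and recovers absolute fold changes.
"""

from metaquin.validation import load_normalization_experiment

result = load_normalization_experiment(seed=7)

print("sequin read fraction phi per sample (halves as load doubles):")
for sample, phi in result["phi"].items():
    print(f"  {sample}: {phi:.4f}")
print(f"\nobserved vs expected LFC over {result['n_comparisons']} "
      f"species/sample-pair comparisons:")
print(f"  sequin (absolute) normalization: R^2 = "
      f"{result['r_squared_absolute']:.4f}")
print(f"  conventional normalization:      R^2 = "
      f"{result['r_squared_conventional']:.4f}")
print("Conventional normalization scatters because A1/A2/A3 (and B1/B2/B3) "
      "are indistinguishable to it; the sequin-rescaled index tracks true "
      "absolute changes.")
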