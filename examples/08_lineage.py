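"""Follow a lineage over generations with parameter noise.

Each cell runs a quasi-static cycle, divides, and its daughters inherit
tip activity; lognormal noise on (epsilon, beta) models cell-to-cell
variability.
"""
from growthzones import GrowthLaw, NoiseModel, NondimParams, simulate_lineage

params = NondimParams(0.070352, 20.0, (0.5, 0.5))
records, summary = simulate_lineage(
    params, generations=3, l_birth=1.05,
    growth_law=GrowthLaw("linear_l", 1.0, 30),
    noise_model=NoiseModel(cv_eps=0.08, cv_beta=0.08), seed=7,
)
print(summary.to_string())
print("Counts per generation and growth pattern: with wild-type-like")
print("parameters essentially every cell shows monopolar growth then NETO;")
print("rerunning with the same seed reproduces the table exactly.")
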