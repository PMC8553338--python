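"""Generate study-like synthetic data and recover parameters from it.

Simulates both genotypes under the default pulse, samples the five
observables at 0, 0.5, 2 and 4 h with three lognormal-noise replicates
(cv = 0.1), then re-estimates the Il6 transcription and degradation
rates (k1, d1) by log-least squares, starting well away from the truth.
"""

from reg1dyn import FitSpec, ModelKind, NoiseSpec, fit, generate_dataset
from reg1dyn.defaults import default_parameters, default_signal_profile

params = default_parameters()
profile = default_signal_profile()

table = generate_dataset(params, params, profile,
                         noise=NoiseSpec(cv=0.1, seed=42, replicates=3))
print(f"synthetic table: {len(table.data)} measurements "
      "(2 genotypes x 4 times x 5 observables x 3 replicates)")
print(table.data.head(6).to_string(index=False))

spec = FitSpec(
    free_parameters=("k1", "d1"),
    bounds={"k1": (0.01, 10.0), "d1": (0.01, 10.0)},
    fixed_values=params,
    model=ModelKind.MODEL_1,
)
result = fit(spec, table, profile, start={"k1": 1.5, "d1": 0.7}, seed=42, n_starts=1)

print(f"\ntrue k1 = {params.k1}, d1 = {params.d1}")
print(f"estimates: k1 = {result.estimates['k1']:.4f}, "
      f"d1 = {result.estimates['d1']:.4f} "
      f"(loss {result.loss_value:.3f}, {result.n_evaluations} evaluations)")
print("With 3 replicates of 10%-CV noise the two-parameter subset is "
      "typically recovered to within ~10-20%; the full 15-parameter model "
      "is not identifiable from this design and is deliberately not fitted.")
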