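"""Simulate a study-shaped screening cohort and check that the classifier
recovers what was injected.

The generator plants a known anisometropia rate per school cycle (rising
2.9% -> 9.4%), a known type mix, and 0.25 D replicate measurement noise;
the pipeline then has to find those cases back from the noisy replicate
readings alone.
"""

from anisoprev import SimulationConfig, classify_frame, simulate_cohort
from anisoprev.cohort_io import average_frame

config = SimulationConfig(n=5000, noise_sd=0.25)
cohort = simulate_cohort(config, seed=42)
labeled = classify_frame(average_frame(cohort.data), config.criteria)

injected = cohort.truth["injected_ta"].mean()
recovered = labeled["is_ta"].mean()
print(f"injected TA prevalence : {100 * injected:.2f}%")
print(f"recovered TA prevalence: {100 * recovered:.2f}%")
print("  the gap is measurement-noise misclassification near the cutoff")

print("\nper-cycle recovered rates (truth pattern rises 2.9% -> 9.4%):")
for cycle, rate in labeled.groupby("cycle")["is_ta"].mean().items():
    print(f"  {cycle:10s} {100 * rate:5.2f}%")

ta = labeled[labeled["is_ta"]]
print("\nrecovered type mix among anisometropes "
      "(configured: 46/33/19/2%):")
for typ, share in ta["aniso_type"].value_counts(normalize=True).items():
    print(f"  {typ:13s} {100 * share:5.1f}%")
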