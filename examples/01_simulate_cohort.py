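"""Generate a synthetic lifespan cohort and inspect its demographics.

The generator draws ages uniformly over 18-87 and gives each subject a
fluid-intelligence score that declines linearly with age plus noise,
clipped to the 0-46 Cattell range — emulating the strong negative
age-cognition correlation seen in lifespan cohorts.
"""
import numpy as np

from isfcpipe import synthgen as sg

cohort = sg.generate_cohort(sg.CohortConfig(n_subjects=500, seed=0))

r = np.corrcoef(cohort["age"], cohort["fluid_intelligence"])[0, 1]
print(f"subjects:            {len(cohort)}")
print(f"age range:           {cohort.age.min()}-{cohort.age.max()} years "
      f"(mean {cohort.age.mean():.1f})")
print(f"males / females:     {int(cohort.sex.sum())} / "
      f"{int((1 - cohort.sex).sum())}")
print(f"fluid intelligence:  {cohort.fluid_intelligence.mean():.1f} "
      f"+/- {cohort.fluid_intelligence.std():.1f} points")
print(f"age-FI correlation:  r = {r:.2f}")
print()
print("r should be strongly negative (about -0.65): older subjects score")
print("lower on the fluid-intelligence test, which the behaviour GLM later")
print("relates to thalamo-cortical ISFC.")
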