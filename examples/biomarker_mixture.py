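"""Population-mean biomarker trajectories from two-phase mixing.

If phase-2 individuals express a marker (say an antimicrobial peptide)
at a high level and phase-1 individuals at a low level, the population
mean rises with age purely because the phase composition shifts — no
individual ever changes expression gradually.
"""

import numpy as np

from twopac import ModelParams, mixture_trajectory

params = ModelParams(a=0.0039, b=-0.019, k=0.1911)
ages = np.array([5.0, 15.0, 25.0, 35.0, 45.0])
m = mixture_trajectory(params, level_phase1=1.0, level_phase2=8.0, ages=ages)

print("age (d)   mean marker level")
for t, v in zip(ages, m):
    print(f"  {t:5.1f}   {v:7.3f}")
print("The apparent 'progressive' increase is a composition effect:")
print("each living fly expresses either 1.0 (phase 1) or 8.0 (phase 2).")
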