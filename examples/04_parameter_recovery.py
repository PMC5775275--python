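"""Recover rate constants from synthetic data by pattern search.

Generates noiseless Asn/Glu time courses from the TaASN2 fitted constants,
then refits k1 (glutamine binding) and kD (ammonia-complex dissociation) by
Hooke–Jeeves pattern search in log10 space, starting at twice the generating
values with k2–k4 held fixed.  Sub-0.1% relative errors demonstrate that the
two enzyme-specific constants are identifiable from the 7-point assay design
densified to 100 time points.
"""

import json

from asnkin import recovery_experiment

report = recovery_experiment("TaASN2", n_points=100, noise_cv=0.0, seed=0)
print(json.dumps(report["parameters"], indent=2))
print(f"\nSSE at the optimum: {report['sse']:.3e} "
      f"after {report['n_evaluations']} objective evaluations")
print("Relative errors below 5% mean the estimation pipeline would faithfully "
      "recover these constants from data of this design.")
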