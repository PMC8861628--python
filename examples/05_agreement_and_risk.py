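"""Inter-annotator agreement and the risk-display formulas.

Simulates three annotators labelling concepts as relevant/irrelevant at a
controlled agreement level, scores them with nominal Krippendorff's alpha
and the centered-cosine correlation distance, and evaluates the two
hospitalization-risk display formulas on a worked 61% -> 44% scenario.
"""

import numpy as np

from kgemr import (absolute_risk_reduction, correlation_distance,
                   krippendorff_alpha, relative_risk_gain,
                   simulate_annotators)

universe = [f"concept_{i}" for i in range(285)]
for agreement in (1.0, 0.8, 0.5):
    m = simulate_annotators(universe, n_annotators=3, agreement=agreement,
                            seed=0)
    alpha = krippendorff_alpha(m.cells)
    v1 = (m.row("A_1") == "relevant").astype(float)
    v2 = (m.row("A_2") == "relevant").astype(float)
    d = correlation_distance(v1, v2)
    counts = [int((m.cells[i] == "relevant").sum()) for i in range(3)]
    print(f"agreement={agreement:.1f}: alpha={alpha:+.3f}, "
          f"corr distance A1-A2={d:.3f}, relevant counts={counts} "
          f"(mean {np.mean(counts):.0f})")

p0, p1 = 61, 44
print(f"\nrisk {p0}% -> {p1}% when treating the selected factors:")
print(f"  absolute reduction: {absolute_risk_reduction(p0, p1):.0f} points")
print(f"  relative gain: {relative_risk_gain(p0, p1)}%")

# alpha is 1 at perfect copying and near 0 at coin-flip agreement; the
# correlation distance ranges over [0, 2] with 0 meaning identical
# annotation patterns. The two risk numbers are what a physician (point
# decrease) and a patient (relative gain) see for the same prediction.
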