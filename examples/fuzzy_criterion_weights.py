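"""Turn linguistic criterion importances into a crisp weight vector.

Shows the five-level triangular fuzzy scale, the Yager defuzzified value of
each level, and the normalized weights for the standard ten-criterion
assignment (six Very High performance metrics, three High usability
criteria, one Medium).
"""

from modelrank import DEFAULT_SCALE, defuzzify_yager, weights_from_linguistic
from modelrank.decision_matrix import CRITERIA_ORDER, DEFAULT_WEIGHT_LABELS

print("Linguistic scale (l, m, u) and Yager index (l + 2m + u)/4:")
for label, tfn in DEFAULT_SCALE.items():
    print(f"  {label:10s} ({tfn.lower}, {tfn.mode}, {tfn.upper})"
          f"  ->  {defuzzify_yager(tfn):.4f}")

labels = [DEFAULT_WEIGHT_LABELS[name] for name in CRITERIA_ORDER]
weights = weights_from_linguistic(labels)

print("\nNormalized weights for the ten standard criteria:")
for name, label, w in zip(CRITERIA_ORDER, labels, weights):
    print(f"  {name:24s} {label:10s} w = {w:.6f}")
print(f"  {'':24s} {'sum':10s}     {weights.sum():.6f}")
print("\nA higher linguistic label always yields a larger weight; the "
      "vector sums to one so outranking flows stay in [-1, 1].")
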