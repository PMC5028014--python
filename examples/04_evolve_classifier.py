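"""Evolve a CGP classifier and read off its decision rule.

Draws a two-class feature table whose class means follow the observed
treatment trend (control-like cells faster and more persistent than
ATP-treated ones), evolves a classifier with the standard configuration
(70 columns, population 10, 1% point mutation) and prints the training
accuracy, the evolved mathematical expression and the features it uses —
the expression is the classifier, directly interpretable.
"""

from cellmot import EvolutionParams, FeatureTableConfig, evolve, generate_feature_table
from cellmot.simulate import FEATURE_NAMES

df = generate_feature_table(FeatureTableConfig(seed=5))
X = df[FEATURE_NAMES].to_numpy(float)
y = df["label"].to_numpy()

clf, trace = evolve(X, y, EvolutionParams(seed=5), feature_names=FEATURE_NAMES)
expr, used = clf.expression()

print(f"training accuracy: {trace[-1]:.3f} after {len(trace) - 1} generations")
print(f"decision rule (classify '{clf.positive_label}' iff value > 0):")
print(f"  {expr}")
print(f"features used: {', '.join(FEATURE_NAMES[i] for i in sorted(used))}")
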