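"""The sparse multi-instance SVM on a hand-sized problem.

Two negative instances and one 2-instance positive bag in the plane. The
positive bag's margin is (2-|B|)/|B| = 0, so its mean vector must only land
on the non-negative side of the hyperplane. The printed weights solve the
quadratic program exactly: w = (0.5, 0), b = -1.
"""

import numpy as np

from cellkine.classifier import confidence, train_smil

negative_instances = np.array([[0.0, 0.0], [0.0, 1.0]])
positive_bag = np.array([[2.0, 0.0], [2.0, 1.0]])

model = train_smil([negative_instances, positive_bag], ["negative", "positive"], C=1.0)
print(f"w = {np.round(model.weights, 6)}, b = {model.bias:.6f}")
print(f"objective value = {model.objective_:.6f}  (0.5*||w||^2, no slack needed)")
print(f"positive-bag raw score  = {model.raw_score(positive_bag):+.6f} (on the boundary)")
print(f"negative-instances score= {model.raw_score(negative_instances):+.6f} (at the margin)")
print(f"calibrated confidences: pos {confidence(model, positive_bag):.3f}, "
      f"neg {confidence(model, negative_instances):.3f}")
print("-> larger positive bags get laxer margins; negatives are constrained per instance")
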