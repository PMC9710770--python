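"""Performance evaluation from a 4x4 confusion matrix.

Builds a report — per-class sensitivity/specificity, overall accuracy and
its exact (Clopper-Pearson) binomial 95% CI — from raw predicted x observed
counts, the way field-validation studies summarise a test set.
"""

import pandas as pd

from accelstates import STATES
from accelstates.classify_eval import evaluate_confusion

# predicted rows x observed columns, state order:
# aquatic-motionless, terrestrial-motionless, aquatic-in-motion, terrestrial-in-motion
counts = [
    [33, 0, 0, 0],
    [18, 242, 0, 4],
    [22, 0, 41, 0],
    [10, 1, 13, 464],
]
matrix = pd.DataFrame(counts, index=list(STATES), columns=list(STATES))
report = evaluate_confusion(matrix)
print(report.to_text())
print()
print(
    "Sensitivity is the fraction of each observed state recovered;\n"
    "specificity the fraction of other states not mislabelled as it.\n"
    "The CI inverts the binomial tail probabilities (no normal approximation)."
)
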