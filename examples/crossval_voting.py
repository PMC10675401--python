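"""Run the full dual-signal protocol with the five-voter ensemble.

Simulates a small paired benchmark, extracts both feature spaces, performs
per-fold LASSO/SDA selection, trains the binary-relevance RBF banks, fuses
them by centralized voting, and prints the cross-validated report.
Takes ~half a minute.
"""

import numpy as np

from locfuse import CLASS_ORDER
from locfuse.pipeline import run_pipeline

report, manifest = run_pipeline(
    {
        "source": {"type": "simulate", "n_per_class": 8, "seed": 1, "separation": 1.0},
        "seq_operators": ["dp_pssm", "pc"],
        "cv": {"scheme": "kfold", "folds": 4},
        "seed": 1,
    }
)

print(f"fused 4-fold CV: accuracy={report.accuracy:.3f} "
      f"precision={report.precision:.3f} recall={report.recall:.3f}")
print("per-voter mean accuracy:")
for name, accs in report.per_voter_fold_accuracy.items():
    print(f"  {name:24s} {float(np.mean(accs)):.3f}")
print("confusion (rows=true, order " + "/".join(CLASS_ORDER) + "):")
print(report.confusion)
# With a strongly separated synthetic signal every voter approaches 1.0 and
# the fused decision matches or beats the best single signal.
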