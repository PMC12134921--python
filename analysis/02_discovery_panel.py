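"""Paired-sample biomarker discovery and the logistic panel.

Screens each marker with a paired t-test and ROC AUC on stable
versus exacerbation log concentrations (selection rule AUC >= 0.59
or <= 0.41 and p < 0.05), fits the backward-stepwise logistic panel,
and reports its operating characteristics with prevalence-adjusted
predictive values at 50% prevalence.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import demo_config
from exalarm.pipeline import run_pipeline

report = run_pipeline(demo_config(["simulate", "discover"]))
d = report["discover"]
print(f"markers passing the screen: {d['selected']}")
print(f"panel retained by backward stepwise: {d['retained']}")
print(f"panel ROC AUC {d['auc']:.2f} (95% CI {d['auc_ci'][0]:.2f}-{d['auc_ci'][1]:.2f})")
print(f"at cut-off {d['cutoff']}: sensitivity {d['sensitivity']:.1f}%, "
      f"specificity {d['specificity']:.1f}%")
print(f"prevalence-adjusted (50%): PPV {d['ppv_50']:.1f}%, NPV {d['npv_50']:.1f}%")
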