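"""Traffic-light decision rules and event-level evaluation.

Daily risk scores become green/amber/red outcomes (amber at or below
13.4 predicted days; red when >= 6 of the trailing 7 days are
amber/red); consecutive red days merge into called events which are
scored against the clinician diagnoses with a 13-day window, and the
windowed ROC of the risk score is reported.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import ALL_STAGES, demo_config
from exalarm.pipeline import run_pipeline

report = run_pipeline(demo_config(ALL_STAGES))
a = report["alarm"]
print(f"events: TP {a['tp']}, FN {a['fn']}, FP {a['fp']}; "
      f"stable days {a['n_stable_days']} (TN {a['tn']})")
print(f"event-level PPV {a['ppv']:.1f}%, NPV {a['npv']:.2f}%" if a['tp'] + a['fp']
      else f"no called events; NPV {a['npv']:.2f}%")
lt = a["lead_times"]
if lt["n"]:
    print(f"lead time: median {lt['median']:.0f} days "
          f"(IQR {lt['iqr_low']:.0f}-{lt['iqr_high']:.0f}, n={lt['n']})")
e = report["evaluate"]
if e.get("windowed_auc") is not None:
    print(f"13-day-window ROC AUC {e['windowed_auc']:.2f} "
          f"(95% CI {e['auc_ci'][0]:.2f}-{e['auc_ci'][1]:.2f}) "
          f"over {e['n_days']} scored days")
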