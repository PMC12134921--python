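"""Build the rolling-window temporal feature database.

Each 14-point window (anchor-13 ... anchor) yields 42 values per
marker (daily value, differential, window-local integral) labelled
with the days to the next exacerbation (200 for none).  Development
windows are the pre-event run-ups plus sampled stable days; the
blinded production set holds recovery spans and all windows of
patients without events.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import demo_config
from exalarm.pipeline import run_pipeline

report = run_pipeline(demo_config(["simulate", "fit_dlm", "features"]))
f = report["features"]
print(f"development windows: {f['n_development']}")
print(f"production (blinded) windows: {f['n_production']}")
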