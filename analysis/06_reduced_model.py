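"""Robustness check: the eight-unit rate model reproduces the PCA
structure of the conductance-based network (stable rotation/translation
components when connected; four-quadrant geometry when disconnected).
"""

import json

from common import make_config
from lptcnet.experiments import run

cfg = make_config("reduced_check", __doc__, default_trials=10)
bundle = run(cfg)
print(json.dumps(bundle["summary"], indent=2, default=str))
print(f"Per-trial table in {cfg.out_dir}/reduced_check_pca.csv")
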