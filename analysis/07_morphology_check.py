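"""Robustness to morphology: two-thirds-length cells keep the population
code (stable in-phase / out-of-phase PC identities in the connected
network)."""

import json

from common import make_config
from lptcnet.experiments import run

cfg = make_config("morphology_check", __doc__, default_trials=10)
bundle = run(cfg)
print(json.dumps(bundle["summary"], indent=2, default=str))
print(f"Per-trial table in {cfg.out_dir}/morphology_check_pca.csv")
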