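"""Population coding of binocular motion: PCA of six-cell rate vectors.

Per trial, pools 150 ms firing-rate vectors of the six spiking cells
across the four stimuli and decomposes them; compares the connected and
disconnected networks (PC identities, PC1−PC2 contribution gap,
quadrant geometry).
"""

import json

from common import make_config
from lptcnet.experiments import run

cfg = make_config("population_pca", __doc__, default_trials=10)
bundle = run(cfg)
print(json.dumps(bundle["summary"], indent=2, default=str))
print(f"Per-trial table in {cfg.out_dir}/population_pca_pca.csv")
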