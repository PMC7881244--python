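"""Recurrence-score calculation from a configuration file.

The calculator treats the published coefficients as data: gene groups with
weights, reference genes for normalization, and an affine calibration. This
example uses the bundled SYNTHETIC config (schema illustration only) on a
small synthetic matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tmesig import ExpressionMatrix, oncotype_dx

cfg = yaml.safe_load(
    (Path(__file__).parent / "oncotype_config_synthetic.yaml").read_text()
)
genes = cfg["reference_genes"] + [
    g for grp in cfg["groups"].values() for g in grp["genes"]
]
rng = np.random.default_rng(8)
mx = ExpressionMatrix(
    pd.DataFrame(
        rng.normal(7, 0.5, size=(len(genes), 6)),
        index=genes, columns=[f"s{i + 1}" for i in range(6)],
    )
)

scores = oncotype_dx(mx, cfg)
print(scores.round(2).to_string())
print("\ncategory counts:", scores["category"].value_counts().to_dict())
# rs is the affine-calibrated weighted sum of reference-normalized group
# means; categories split at 30 and 40 (boundary 40 stays intermediate).
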