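"""Compare the five variant-weighting schemes on one simulated region.

Each variant is classified risk/nonrisk by its case-control minor-allele
imbalance and weighted by: RM (Poisson likelihood-ratio risk measure),
WSt (Madsen-Browning control-frequency), Fp (pooled-frequency), RBt
(replication-based binomial tail) and EREC (estimated regression
coefficient).  Strongly imbalanced variants earn large RM/RBt/EREC
weights; WSt and Fp reward rarity regardless of direction.
"""

import numpy as np
import pandas as pd

import bsvm

scenario = bsvm.Scenario(n_risk=4, n_protective=2, n_neutral=4,
                         total_par=0.02, n1=500, n2=500)
rng = np.random.default_rng(11)
truth = bsvm.simulate_truth(scenario, rng)
data = bsvm.generate_dataset(scenario, rng, truth=truth)
data, _ = bsvm.drop_monomorphic(data)

tables = []
for scheme in ["RM", "WSt", "RBt", "Fp", "EREC"]:
    summaries = bsvm.compute_weights(data, scheme=scheme)
    tab = bsvm.weights_table(summaries, scheme)
    tables.append(tab.set_index("variant_id")["weight"].rename(scheme))
base = bsvm.weights_table(bsvm.compute_weights(data, scheme="RM"), "RM")
out = pd.concat([base.set_index("variant_id")[
    ["m_case", "m_ctrl", "category"]]] + tables, axis=1)
out.insert(0, "role", [dict(zip(truth.variant_id, truth.role))[v]
                       for v in out.index])
print(out.round(3).to_string())
# Risk variants (minor allele enriched in cases) should show category
# "risk" and the largest RM weights; the rarest variants get the largest
# WSt/Fp weights whatever their direction.
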