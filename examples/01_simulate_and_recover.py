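"""Plant a directed gene network, simulate expression, and recover it.

Builds a 30-gene network with 15 signed edges, simulates 60 expression
profiles from it, runs the swarm (25 Monte Carlo resamples, one 2-hidden-unit
tanh perceptron per resample and output gene) and reports how well the
inferred influence matrix recovers the planted structure.
"""

import numpy as np

from netswarm import planted_recovery

run = planted_recovery(generator_seed=11, noise_sd=0.5)

print(f"planted edges          : {run.network.n_edges}")
print(f"edge-recovery AUROC    : {run.auroc:.3f}")
print(f"sign recovery          : {run.sign_recovery:.0%}")
top = np.unravel_index(np.argmax(np.abs(run.result.mean_influence)), run.result.mean_influence.shape)
print(
    f"strongest inferred edge: {run.result.gene_ids[top[0]]} -> {run.result.gene_ids[top[1]]}"
    f" (influence {run.result.mean_influence[top]:+.3f},"
    f" sign consistency {run.result.sign_consistency[top]:.2f})"
)

# AUROC near 1 means planted gene pairs outrank absent pairs almost perfectly;
# sign recovery is the share of planted edges whose inferred influence has the
# planted sign (activating vs. repressive).
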