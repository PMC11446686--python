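"""Validate a candidate gene with qPCR arithmetic: 2^-ddCt plus t tests.

Builds a small cycle-threshold (Ct) table for one target gene and one
housekeeping gene across young and aged samples, computes per-sample relative
expression with the comparative-Ct method, and compares groups with a Welch
t test (and a paired t test for a pre/post design).
"""

import numpy as np

from netswarm import QpcrTable, delta_delta_ct, paired_t_test, welch_t_test

rng = np.random.default_rng(3)
n = 8  # samples per group
# aged samples amplify the target ~1 cycle earlier -> roughly 2x expression
target_ct = np.concatenate([25.0 + rng.normal(0, 0.3, n), 24.0 + rng.normal(0, 0.3, n)])
gapdh_ct = 20.0 + rng.normal(0, 0.2, 2 * n)

table = QpcrTable(
    gene_ids=["FST", "GAPDH"],
    sample_ids=[f"s{i}" for i in range(2 * n)],
    ct_values=np.vstack([target_ct, gapdh_ct]),
    group_labels=["young"] * n + ["aged"] * n,
    reference_genes=["GAPDH"],
)

rel = delta_delta_ct(table, "FST", calibrator_group="young")
young = [r.rq for r in rel if r.group_label == "young"]
aged = [r.rq for r in rel if r.group_label == "aged"]
print(f"mean RQ young: {np.mean(young):.2f} (calibrator group, ~1 by construction)")
print(f"mean RQ aged : {np.mean(aged):.2f} (fold change vs. young)")

t, df, p = welch_t_test(young, aged)
print(f"Welch t test : t={t:.3f}, df={df:.1f}, p={p:.2g}")

# a paired pre/post comparison on the same subjects
pre, post = np.array(young), np.array(young) + rng.normal(0.8, 0.3, n)
t, df, p = paired_t_test(pre, post)
print(f"paired t test: t={t:.3f}, df={df:.0f}, p={p:.2g}")

# RQ is relative quantity 2^-ddCt: Ct normalized to the housekeeping gene,
# then to the calibrator group's mean; p < 0.05 flags a group difference.
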