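"""Relative expression by 2^-ddCt with two reference genes.

Target Ct values are normalised against the mean of the reference-gene
Cts (the geometric mean of reference quantities at efficiency 2); the
fold change is 2^-ddCt between stress and control, with a two-sided
t-test across biological replicates.
"""

import pandas as pd

from est454 import relative_expression
from est454.qpcr import significance_stars

rows = []
for cond, shift in (("control", 0.0), ("stress", -2.0)):  # 2 cycles = 4-fold up
    for rep in (1, 2):
        sample = f"root_{cond}_{rep}"
        offset = 0.05 * rep  # sample-wide pipetting offset, cancels in dCt
        bio = 0.2 if rep == 2 else -0.2  # biological scatter of the target
        for gene, ct in (("GAPDH2", 19.8), ("PP2A1", 22.1),
                         ("ALDH", 24.0 + shift + bio)):
            for tech in (0.0, 0.1):  # technical duplicates
                rows.append({"gene": gene, "sample": sample,
                             "condition": cond, "tissue": "root",
                             "replicate": rep, "ct": ct + offset + tech})
ct_table = pd.DataFrame(rows)

(result,) = relative_expression(ct_table, targets=["ALDH"],
                                refs=["GAPDH2", "PP2A1"])
print(f"gene {result.gene} ({result.tissue}), "
      f"n = {result.n_replicates} biological replicates")
print(f"fold change (stress / control): {result.fold_change:.2f} "
      f"{significance_stars(result.p_value)}")
print(f"t-test p-value: {result.p_value:.4g}")
# A 2-cycle earlier Ct under stress is a 4-fold induction; reference-gene
# normalisation cancels sample-wide Ct offsets before the comparison.
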