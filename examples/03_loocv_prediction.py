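"""Cross-validated prediction of the four subtests from one modality.

Compares the two VIP-selection protocols: "paper" selects high-VIP
features once on the full data before cross-validation; "nested"
re-selects inside every leave-one-out fold and is leakage-free. The gap
between them quantifies selection optimism.
"""

import numpy as np

from lesionpls import CohortSpec, generate_cohort, vip_restricted_cv

cohort = generate_cohort(CohortSpec(seed=7))
md = cohort.modalities["md"]

for mode in ("paper", "nested"):
    cv = vip_restricted_cv(
        md.values, cohort.behaviour.scores, "md", md.feature_labels,
        mode=mode, subtests=cohort.behaviour.subtests,
    )
    print(f"\nselection mode: {mode}")
    for name, r, p in zip(cv.subtests, cv.r, cv.p_value):
        print(f"  {name:24s} r = {r:5.2f}   p = {p:.2g}")

print("\nr is the Pearson correlation between observed scores and the")
print("out-of-fold predictions; nested r is the honest accuracy estimate.")
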