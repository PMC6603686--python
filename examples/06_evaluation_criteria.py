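"""Grade a BP estimator against AAMI, BHS and Bland-Altman criteria.

Builds a mock test set whose predictions err with 3 mmHg standard
deviation, then prints the full agreement report: MAD/STD/MSE, Pearson
r^2, the cumulative error percentages at 5/10/15 mmHg with the BHS grade
(A needs 60/85/95), the AAMI verdict (MAD <= 5 and STD <= 8 mmHg), and the
Bland-Altman mean difference and 95% limits of agreement.
"""

import json

import numpy as np

from pttbp import evaluate

rng = np.random.default_rng(0)
sbp_true = rng.normal(125.0, 15.0, 500)
sbp_pred = sbp_true + rng.normal(0.5, 3.0, 500)

report = evaluate(sbp_true, sbp_pred)
print(json.dumps(report.to_dict(), indent=1))
print(f"\nBHS grade {report.bhs}: "
      f"{report.pct_within_5:.1f}% / {report.pct_within_10:.1f}% / "
      f"{report.pct_within_15:.1f}% within 5/10/15 mmHg")
print(f"AAMI {'pass' if report.aami_pass else 'fail'} "
      f"(MAD {report.mad:.2f} <= 5 and STD {report.std:.2f} <= 8)")
print(f"Bland-Altman: mean diff {report.ba_mean_diff:+.2f} mmHg, "
      f"limits [{report.ba_lower:.2f}, {report.ba_upper:.2f}], "
      f"{100*report.ba_fraction_within:.1f}% within")
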