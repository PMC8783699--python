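"""BHS and AAMI device-standard grading of blood-pressure estimates.

Grades a simulated estimator (noise SD 5 mmHg, bias +2 mmHg) against the
British Hypertension Society cumulative-error bands and the AAMI
mean-error/SD criterion, and prints the Bland-Altman limits of agreement.
"""

import numpy as np

from bpcluster import aami_check, bhs_grade, bland_altman

rng = np.random.default_rng(1)
reference = rng.uniform(90, 160, 2000)
estimate = reference + rng.normal(2.0, 5.0, reference.size)

pct5, pct10, pct15, grade = bhs_grade(estimate, reference)
print(f"BHS cumulative percentages: <=5 mmHg {pct5:.2f}%  "
      f"<=10 mmHg {pct10:.2f}%  <=15 mmHg {pct15:.2f}%  ->  grade {grade}")

me, sd, ok = aami_check(estimate, reference, n_subjects=100)
print(f"AAMI: mean error {me:.3f} mmHg, SD {sd:.3f} mmHg, 100 subjects -> "
      f"{'pass' if ok else 'fail'} (requires |ME| <= 5, SD <= 8, n >= 85)")

bias, lo, hi = bland_altman(estimate, reference)
print(f"Bland-Altman: bias {bias:.3f} mmHg, limits of agreement "
      f"[{lo:.3f}, {hi:.3f}] mmHg (bias +/- 1.96 SD)")
print("A grade-A device needs 60/85/95% of errors within 5/10/15 mmHg;",
      "this simulated estimator clears those bands.")
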