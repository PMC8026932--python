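"""Recurrence-free survival by predicted group.

Draws survival outcomes for a synthetic cohort whose predictions equal the
true class (the best case a classifier could achieve), fits Kaplan-Meier
curves per predicted group and runs the log-rank test.  The milestone table
shows the 2/3/5-year recurrence-free survival read off the step functions;
a small log-rank p means the predicted groups have genuinely different
hazards.
"""

import numpy as np

from qusrecur import survival

rng = np.random.default_rng(4)
n_rec, n_non = 17, 34
t_rec = np.minimum(rng.exponential(13.0, n_rec) + 0.1, 64.0)
t_non = np.minimum(rng.exponential(60.0, n_non) + 0.1, 64.0)
events = np.concatenate([t_rec < 64.0, np.zeros(n_non, bool)])
times = np.concatenate([t_rec, t_non])
pred = np.array(["recurrence"] * n_rec + ["no_recurrence"] * n_non)

res = survival.rfs_by_predicted_group(pred, times, events)
print(f"log-rank chi2 = {res['logrank_statistic']:.2f}, "
      f"p = {res['logrank_p']:.2g}")
for group in ("no_recurrence", "recurrence"):
    ms = res["milestones"][group]
    vals = ", ".join(f"{int(m)} mo: {100*s:.0f} %"
                     for m, (s, _) in sorted(ms.items()))
    print(f"predicted {group:14s} RFS  {vals}")
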