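"""Hyper/hypo-editing survival association in a simulated patient cohort.

Simulates 86 patients whose progression hazard rises with the editing level
at one driver site (log-hazard 3 per unit level) plus one null site,
classifies each patient HYPER/HYPO about the per-site cohort mean, and runs
the Kaplan-Meier / log-rank scan.
"""

import numpy as np
import pandas as pd

from editscape.simulate import SurvSimConfig, gen_survival
from editscape.survival import site_survival_scan

rng = np.random.default_rng(12)
patients = pd.Index([f"p{i:03d}" for i in range(1, 87)], name="patient_id")
levels = pd.DataFrame(
    {"driver_site": rng.beta(0.5, 0.5, 86), "null_site": rng.beta(0.5, 0.5, 86)},
    index=patients,
)
surv = gen_survival(levels["driver_site"], SurvSimConfig(seed=13))

summary, details = site_survival_scan(levels, surv)
print(summary.round(4).to_string(index=False))
print("\nKaplan-Meier head (driver site, hyper-edited arm):")
print(details["driver_site"].km_hyper.head(6).round(4).to_string(index=False))

# The driver site should show a small log-rank p-value (hyper-edited
# patients progress faster by construction), while the null site should
# not; n_hyper + n_hypo equals the patients with the site observed, and the
# KM table tracks at-risk counts, events, and the survival step function.
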