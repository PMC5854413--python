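"""Method-agreement statistics on a paired SUR table.

Builds a small synthetic manual-vs-automatic SUR table with a known
additive bias, then prints the full agreement panel: Pearson r,
per-subject variability (mean +/- SD), Bland-Altman mean difference with
limits of agreement, and the one-way ICC. The worked percent-error
example uses the printed phantom values 0.77 (manual) and -0.07
(mismatched-template automatic), giving 109.09%.
"""

import numpy as np
import pandas as pd

from datquant import PairedSURTable, agreement_report, percent_error

print(f"percent error (manual 0.77 vs automatic -0.07): "
      f"{percent_error(0.77, -0.07):.2f}%\n")

rng = np.random.default_rng(0)
manual = rng.uniform(0.4, 2.0, 25)
table = PairedSURTable(pd.DataFrame({
    "manual": manual,
    "auto": manual + 0.3 + rng.normal(0, 0.15, 25),   # automatic reads 0.3 higher
}))
rep = agreement_report(table, "auto")
print(f"n                 : {rep.n}")
print(f"Pearson r         : {rep.pearson_r:.3f}")
print(f"variability       : {rep.variability_mean:.3f} +/- {rep.variability_sd:.3f}")
print(f"Bland-Altman bias : {rep.mean_diff:.3f}  (LoA {rep.loa_low:.3f} .. {rep.loa_high:.3f})")
print(f"ICC(1,1)          : {rep.icc:.3f}  (MSBS {rep.icc_components.msbs:.3f}, "
      f"MSWS {rep.icc_components.msws:.3f})")
print("\nThe systematically higher automatic method shows a negative")
print("Bland-Altman bias (manual - automatic) and an ICC well below the")
print("Pearson r: correlation survives an additive offset, agreement does not.")
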