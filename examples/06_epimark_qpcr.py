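"""Quantify per-locus 5hmC / 5mC / unmodified fractions from qPCR copies.

Beta-glucosyltransferase (BGT) glucosylates 5hmC, protecting it from MspI;
HpaII cuts only unmodified CCGG. Background (the fully-cuttable mock+MspI
signal) is subtracted and everything is normalised to the undigested
glucosylated sample, giving 5hmC and 5hmC+5mC fractions directly.
"""

import pandas as pd

from hydroxyscan import SyntheticConfig
from hydroxyscan.epimark import modification_table
from hydroxyscan.synthetic import simulate_qpcr

truth = pd.DataFrame({
    "locus": ["peak_1", "peak_2", "peak_3", "control_1", "control_2"],
    "hmc": [0.364, 0.20, 0.096, 0.027, 0.005],
    "mc": [0.25, 0.40, 0.30, 0.45, 0.50],
})
config = SyntheticConfig(qpcr_noise_cv=0.05, qpcr_replicates=3, seed=9)
qpcr = simulate_qpcr(truth, config)
table = modification_table(qpcr).merge(truth, on="locus")

print(f"{'locus':>10}  {'5hmC est':>9}  {'truth':>6}  {'5mC est':>8}  {'truth':>6}")
for _, row in table.iterrows():
    print(f"{row['locus']:>10}  {row['hmc_fraction']:9.3f}  {row['hmc']:6.3f}"
          f"  {row['mc_fraction']:8.3f}  {row['mc']:6.3f}")
# Estimates track the generating fractions to within a few percent at 5%
# qPCR noise; 'peak' loci show substantial 5hmC while controls are near zero.
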