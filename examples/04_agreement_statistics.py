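"""The agreement battery on toy waveforms.

MAE quantifies absolute error between paired 101-point waveforms; CMC
their shape similarity across protocols; ICC(1,3) trial-to-trial
reproducibility; each value carries its standard interpretation band.
"""

import numpy as np

from gaitval import cmc, icc_1_3, interpret, mae, mae_ci, paired_t, pearson

t = np.linspace(0, 1, 101)
reference = 30 * np.sin(2 * np.pi * t)
measured = reference + np.random.default_rng(0).normal(0, 3.0, size=101)

e = mae(measured, reference)
print(f"MAE = {e:.2f} deg -> {interpret('AE', e)}")

c = cmc(np.vstack([measured, reference]))
print(f"CMC = {c:.3f} -> {interpret('CMC', c)}")

rng = np.random.default_rng(1)
subjects = rng.normal(30, 6, size=(21, 1)) + rng.normal(0, 2, size=(21, 3))
icc, lo, hi = icc_1_3(subjects)
print(f"ICC(1,3) = {icc:.3f} [{lo:.3f}, {hi:.3f}] -> {interpret('ICC', icc)}")

maes = rng.normal(3.1, 0.9, size=21)
m, lo, hi = mae_ci(maes)
print(f"cohort MAE = {m:.2f} ({lo:.2f}-{hi:.2f}) deg over 21 participants")

r, p = pearson(subjects.mean(axis=1), subjects.mean(axis=1) + rng.normal(0, 1, 21))
tstat, tp = paired_t(maes, maes + rng.normal(0.5, 0.5, 21))
print(f"Pearson r = {r:.3f} (p = {p:.2g}); paired t = {tstat:.2f} (p = {tp:.2g})")
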