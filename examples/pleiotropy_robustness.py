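"""How the estimator suite behaves when instruments are invalid.

Simulates 200 datasets in which 40% of instruments carry a directional
pleiotropic effect (mean 0.02 on the log-odds scale) alongside a true causal
effect of 0.2, and compares the estimators: IVW absorbs the pleiotropy into
its estimate, the weighted median resists it while a majority of weight is
valid, and the MR-Egger intercept estimates the average pleiotropic effect.
"""

from mratlas.calibration import robustness_under_pleiotropy

out = robustness_under_pleiotropy(
    n_reps=200, theta=0.2, invalid_fraction=0.4,
    pleiotropy_mean=0.02, pleiotropy_sd=0.01, seed=3,
)

print(f"true causal effect:            0.200")
print(f"IVW bias:                     {out['ivw_bias']:+.4f}")
print(f"weighted-median bias:         {out['weighted_median_bias']:+.4f}")
print(f"mean Egger intercept:         {out['egger_intercept_mean']:.5f}")
print(f"mean simulated pleiotropy:    {out['true_pleiotropy_mean']:.5f}")
print(f"(intercept Monte-Carlo SE:    {out['egger_intercept_mc_se']:.5f})")

print("\nThe weighted median should be markedly less biased than IVW, and the "
      "Egger intercept should sit within Monte-Carlo error of the simulated "
      "mean pleiotropic effect — the signature used to flag pleiotropic "
      "exposures in the screen.")
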