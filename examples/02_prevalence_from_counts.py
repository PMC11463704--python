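"""Population prevalence from a per-subject significance count.

Given that k of n participants individually reached significance, the
posterior over the population prevalence gamma is summarized by its mode
(MAP) and the 96% highest-posterior-density interval.  The test-calibrated
model accounts for the per-test false-positive rate alpha_fp: even
subjects without the effect reach significance at rate alpha_fp, so the
significance probability is theta = alpha_fp + (1 - alpha_fp) * gamma.
"""

from splitprev import estimate, posterior

for label, k in (("frame-speed condition", 24), ("flash-opacity condition", 27)):
    est = estimate(k, 45, model="test_calibrated", alpha_fp=0.05, mass=0.96)
    m, lo, hi = est.rounded(2)
    print(f"{label}: {k}/45 significant -> "
          f"MAP = {m:.2f}, 96% HPDI = [{lo:.2f}, {hi:.2f}]")

# The simple beta description ignores the false-positive correction: the
# counts are "added to 1" to give a Beta(1 + k, 1 + n - k) posterior.
simple = posterior(24, 45, model="simple_beta")
print(f"\nsimple-beta posterior for 24/45: "
      f"Beta({simple.beta_params.alpha:g}, {simple.beta_params.beta:g}), "
      f"mode {24 / 45:.3f} (no false-positive correction, hence higher "
      "than the calibrated MAP)")
zero = posterior(0, 45, model="simple_beta")
print(f"simple-beta posterior for 0/45:  "
      f"Beta({zero.beta_params.alpha:g}, {zero.beta_params.beta:g})")
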