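"""Run one Bayesian adaptive session against a simulated child observer.

The engine starts from a uniform prior over 38,400 candidate CSFs and, each
trial, presents the (frequency, contrast) pair that minimizes the expected
posterior entropy. The simulated observer answers through the same Weibull
psychometric model with its own true CSF and a small lapse rate. After the
60-trial baseline protocol, the posterior-mean metrics are compared with
the observer's ground truth.
"""

from etgcsf import (
    CSFParams,
    DirectResponder,
    SimObserver,
    aulcsf,
    csf_acuity,
    protocol_preset,
    run_session,
)

truth = CSFParams(gamma_max=60.0, f_max=3.0, beta=3.5, delta=0.6)
observer = SimObserver(true_params=truth, lapse_rate=0.03)
protocol = protocol_preset("exp1")  # 60 valid trials, 0.5-32 cpd

result = run_session(protocol, DirectResponder(observer), seed=11)
est = result.estimate

print(f"protocol {result.protocol}: {result.n_valid} valid trials, "
      f"{result.n_invalid} re-presented")
print("first five presentations (frequency cpd, contrast, outcome):")
for rec in result.records[:5]:
    print(f"  {rec.stimulus.sf:5.2f} cpd  contrast {rec.stimulus.contrast:6.4f}"
          f"  -> {rec.outcome}")

lo, hi = est.ci["aulcsf"]
print(f"\nAULCSF: estimated {est.aulcsf:.3f} (95% CrI {lo:.3f}-{hi:.3f}), "
      f"true {aulcsf(truth):.3f} log units")
alo, ahi = est.ci["csf_acuity_logmar"]
print(f"CSF acuity: estimated {est.csf_acuity_logmar:+.3f} logMAR "
      f"(95% CrI {alo:+.3f}-{ahi:+.3f}), true {csf_acuity(truth).logmar:+.3f}")
print("The acuity interval is wide: this observer's cutoff (57 cpd) lies "
      "beyond the 32 cpd stimulus ceiling, so it is posterior extrapolation.")
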