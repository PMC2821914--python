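"""ThT fibrillization kinetics: sigmoid fits and lag-phase comparison.

Generates triplicate ThT curves (5-minute sampling over 100 h) for two
samples sharing the same true kinetics, fits each replicate with the
logistic F(t) = F0 + A/(1 + exp(-k(t - t50))), extracts tangent-intercept
lag times (t50 - 2/k), and runs a one-way F-test across samples.
"""

from synucleag import SynthConfig, ThTParams, compare_lags, fit_sigmoid
from synucleag import gen_tht_curves

truth = ThTParams(f0=10.0, amplitude=100.0, t50_h=40.0, rate_per_h=0.2,
                  noise_sd=2.0)
true_lag = truth.t50_h - 2.0 / truth.rate_per_h

lags = {}
for sample, seed in [("syn_alone", 3), ("syn_plus_ligand", 4)]:
    curves = gen_tht_curves(SynthConfig(seed=seed, tht_params=truth),
                            n_replicates=3, sample=sample)
    fits = [fit_sigmoid(c) for c in curves]
    lags[sample] = [f.lag for f in fits if f.converged]
    for f in fits:
        print(f"{sample} rep {f.replicate}: t50={f.t50:5.2f} h  "
              f"k={f.rate:.3f}/h  lag={f.lag:5.2f} h  rmse={f.rmse:.2f}")

print(f"\ntrue lag: {true_lag:.1f} h")
result = compare_lags(lags, alpha=0.05)
for name in result.group_means:
    print(f"{name}: lag {result.group_means[name]:.2f} "
          f"+/- {result.group_sds[name]:.2f} h (n={result.group_ns[name]})")
print(f"one-way F-test p = {result.p_value:.3f} -> {result.verdict}")
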