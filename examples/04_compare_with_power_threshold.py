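"""Compare the coded-vector classifier with the RMS power threshold.

Scores both methods on recordings with balanced and with skewed (~80/20)
state occupancy. The RMS threshold is the experiment-mean window RMS, so
it drifts toward the majority state's amplitude when occupancy is skewed;
the coded-vector classifier keys on band-power ratios and is unaffected.
"""

import cortstate as cs

train_rec, train_truth = cs.simulate_lfp(
    cs.SimConfig(duration_s=400.0, n_channels=4, rng_seed=100))
model = cs.train_classifier(train_rec, train_truth)

experiments = []
balanced = cs.SimConfig(duration_s=400.0, n_channels=4, rng_seed=3)
experiments.append(("balanced", *cs.simulate_lfp(balanced)))
skewed = cs.SimConfig(
    duration_s=400.0, n_channels=4, rng_seed=1,
    dwell_mean_s={cs.SYNCHRONISED: 200.0, cs.DESYNCHRONISED: 45.0},
    initial_state=cs.SYNCHRONISED,
)
experiments.append(("~80/20 skewed", *cs.simulate_lfp(skewed)))

methods = {
    "coded-vector": lambda rec: cs.classify_recording(rec, model),
    "power-threshold": lambda rec: cs.power_threshold_classify(
        cs.rms_windows(rec))[0],
}

for name, rec, truth in experiments:
    occ = max(truth.occupancy().values())
    print(f"\n{name} occupancy (majority state {occ:.0%}):")
    for mname, fn in methods.items():
        row = cs.score(fn(rec), truth)
        print(f"  {mname:16s} total accuracy {row.total_accuracy:6.2f} %")
print("\nBoth methods are near ceiling on balanced data; on skewed data "
      "the power threshold degrades sharply while the coded-vector "
      "classifier holds, which is why band ratios rather than absolute "
      "power are the preferred state marker.")
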