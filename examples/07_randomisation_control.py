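"""Permutation control for the state-sorted haemodynamic difference.

Takes the per-period Hbt means of one long spontaneous experiment,
permutes the state labels 50 times, and asks whether the true
desynchronised-minus-synchronised difference is a Tukey (1.5 x IQR)
outlier of the pooled distribution. With the configured baseline shift
the true difference stands far outside the permutation null; with the
shift disabled it sits inside.
"""

import numpy as np

import cortstate as cs

for effect, label in ((True, "configured +2.0 uM Hbt shift"),
                      (False, "no state effect")):
    shift = ({"hbo": 8.56, "hbr": -5.56, "hbt": 2.00} if effect
             else {"hbo": 0.0, "hbr": 0.0, "hbt": 0.0})
    config = cs.SimConfig(duration_s=2400.0, n_channels=1, rng_seed=0,
                          hemo_baseline_shift=shift)
    truth = cs.simulate_states(config)
    hemo = cs.simulate_hemodynamics(config, truth)

    times = np.arange(0.0, config.duration_s - 1.0, 1.0)
    seg = cs.StateSegmentation(window_times=times,
                               labels=truth.label_at(times),
                               step_s=1.0, window_s=1.0)
    summary = cs.baseline_state_means(hemo, cs.stable_periods(seg))

    values, labels, weights = [], [], []
    for state in (cs.SYNCHRONISED, cs.DESYNCHRONISED):
        for m, dur in zip(summary.period_means[state],
                          summary.period_durations[state]):
            values.append(m["hbt"])
            labels.append(state)
            weights.append(dur)

    rep = cs.randomisation_control(values, labels, n_repeats=50,
                                   rng=np.random.default_rng(1),
                                   weights=weights)
    print(f"\n{label} ({len(values)} stable periods):")
    print(f"  true difference: {rep.true_difference:+.3f} uM")
    print(f"  null differences span [{rep.null_differences.min():+.3f}, "
          f"{rep.null_differences.max():+.3f}] uM")
    print(f"  outlier fences: [{rep.lower_fence:+.3f}, "
          f"{rep.upper_fence:+.3f}] uM")
    print(f"  true difference flagged as outlier: {rep.true_is_outlier}")
print("\nA flagged true difference means the state sorting, not chance "
      "grouping, drives the haemodynamic contrast.")
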