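"""How long does a sleep stage 'remember' itself?

Draws hypnograms from the sticky default transition matrix, computes
the group-averaged normalized autocovariance of each stage's indicator
series, and reports the autocorrelation time t_c - the motivation for
feeding the previous epoch's prediction back into the classifier.
"""

from sleepmem import (STAGES, SyntheticStudyConfig, autocorrelation_time,
                      autocovariance, generate_hypnograms, group_average_autocov,
                      indicator_series)

config = SyntheticStudyConfig(n_subjects=20, epochs_per_subject=1000, seed=3)
hypnograms = generate_hypnograms(config)
delta_t = config.epoch_seconds

print(f"{'stage':>5} {'t_c (min)':>10} {'tau_max (epochs)':>17}")
for stage in STAGES:
    gammas = [autocovariance(indicator_series(h, stage, delta_t), max_lag=120)
              for h in hypnograms]
    rho, se = group_average_autocov(gammas, max_lag=120)
    t_c, tau_max = autocorrelation_time(rho, delta_t)
    print(f"{stage:>5} {t_c / 60:>10.1f} {tau_max:>17d}")
# Stickier stages (large self-transition probability, e.g. N3 at 0.92)
# persist for minutes; an epoch is 0.5 min, so t_c >> 0.5 min means the
# previous stage is highly informative about the current one.
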