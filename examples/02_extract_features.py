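"""Extract the 37-feature vector from stage-conditioned epochs.

Synthesizes one epoch per stage and prints a few features whose
stage-dependence is physiologically interpretable: the delta/alpha power
ratio (deep sleep vs wake), Higuchi fractal dimension (signal
complexity), and the relative energy in the spindle-carrying D3 wavelet
band.
"""

from sleepmem import FEATURE_NAMES, default_emissions, extract_features, \
    synthesize_epoch

RATIO_DA = FEATURE_NAMES.index("ratio_1")  # delta/alpha
HFD = FEATURE_NAMES.index("hfd")
D3_REL = FEATURE_NAMES.index("D3_relative_energy")

print(f"{'stage':>5} {'delta/alpha':>12} {'HFD':>6} {'D3 rel. energy':>15}")
for stage, spec in default_emissions().items():
    epoch = synthesize_epoch(stage, spec, rng_seed=1)
    vec = extract_features(epoch)
    print(f"{stage:>5} {vec[RATIO_DA]:>12.2f} {vec[HFD]:>6.3f} "
          f"{vec[D3_REL]:>15.3f}")
# Expect delta/alpha maximal for N3 (slow-wave sleep); D3 (~8-16 Hz)
# loads on alpha-rich wake and on spindle-rich N2 relative to N1/REM;
# HFD lies between 1 (smooth) and 2 (noise-like).
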