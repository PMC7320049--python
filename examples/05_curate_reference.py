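"""Curate a reference dataset from two asynchronous analyzer streams.

Pair each low-field timestamp with the nearest high-field result, keep only
steady-state windows (11-point moving linear fit), drop pairs disagreeing by
more than 0.04 mol/L, and select a uniformly covering subset by Kennard-Stone.
"""

from nmrcal import (
    kennard_stone_select,
    make_toy_library,
    match_nearest,
    remove_outliers,
    steady_state_mask,
)

lib = make_toy_library(seed=0)
lf, hf = lib.trajectory_lf, lib.trajectory_hf

pairs = match_nearest(lf, hf)
print(f"paired {len(pairs)} low-field rows to {len(hf)} reference rows")

mask = steady_state_mask(lf, window=11, slope_max=0.1, std_max=0.01)
steady = pairs.loc[mask].reset_index(drop=True)
print(f"steady-state filter: {int(mask.sum())}/{len(lf)} rows kept "
      "(plateaus pass, ramps and spikes fail)")

cleaned = remove_outliers(steady, max_dev=0.04)
print(f"outlier filter: removed {len(steady) - len(cleaned)} rows with "
      "|hf - lf| > 0.04 mol/L (simulated calibration-bias episodes)")

hf_cols = [c for c in cleaned.columns if c.startswith("hf_")]
sel = kennard_stone_select(cleaned[hf_cols].to_numpy(), min(30, len(cleaned)))
print(f"Kennard-Stone selected {len(sel)} samples covering concentration space")
print("uniformly — countering the bias of process data towards the set point.")
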