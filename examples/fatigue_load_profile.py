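"""Build the cyclic durability load definition.

The orthosis durability test applies a sinusoidal stretching force at
walking cadence: stress ratio R = 0.1, peak force 50 N, 1 Hz.  The valley
force is R x peak = 5 N.  300,000 cycles correspond to 4 months of use at
2,500 steps per day (one step = one load cycle, 30-day months).
"""

import numpy as np

from afogen import LoadProfileSpec, cycles_from_usage, load_profile, months_of_use

spec = LoadProfileSpec(cycle_count=100)  # 100 cycles are enough to inspect
t, force = load_profile(spec)
peaks = np.nonzero(force == force.max())[0]
print(f"force range : {force.min():.1f} N to {force.max():.1f} N")
print(f"period      : {np.diff(t[peaks]).mean():.3f} s "
      f"({len(peaks)} peaks in {t[-1] + t[1]:.0f} s)")

cycles = cycles_from_usage(steps_per_day=2500, days=4 * 30)
print(f"2500 steps/day for 4 months = {cycles:,} cycles")
print(f"300,000 cycles = {months_of_use(300_000, 2500):.1f} months at 2500 steps/day")
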