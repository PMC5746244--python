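"""Check the Monte Carlo machinery against closed-form synthetic models.

A product-of-uniforms model has an analytic mean and SD, so simulation
error can be measured exactly.  Also exports a kernel-density curve of the
simulated distribution, the raw material for distribution plots.
"""

import math

from cpbsim import SimulationConfig, kde_export, run_simulation
from cpbsim.synth import make_product_chain

n = 100_000
model, ranges, mean, sd = make_product_chain(4, seed=3)
sample = run_simulation(model, ranges, SimulationConfig(n_iterations=n, seed=11))

se = sd / math.sqrt(n)
print(f"analytic mean {mean:.5f}, sd {sd:.5f}")
print(f"simulated mean {sample.mean():.5f}, sd {sample.std(ddof=1):.5f}")
print(f"mean error = {abs(sample.mean() - mean) / se:.2f} MC standard errors")

x, density = kde_export(sample, grid_size=256)
area = sum((density[1:] + density[:-1]) / 2 * (x[1:] - x[:-1]))
print(f"KDE curve: {len(x)} points, peak density {density.max():.2f} "
      f"near x={x[density.argmax()]:.3f}, area {area:.3f} (should be ~1)")
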