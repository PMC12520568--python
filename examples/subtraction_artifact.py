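"""Why subtraction-based 5mC estimation fails at high-5hmC sites.

The legacy approach estimates 5mC as (BS-seq level) - (5hmC level), two
noisy fractions from different libraries.  At modest depth this goes
negative wherever true 5mC is low and 5hmC high.  The direct CD-seq
estimate is a single binomial fraction and stays in [0, 1] by
construction, with smaller variance at equal depth.
"""

import numpy as np
import pandas as pd

from duomod import calling, pairing
from duomod import simulate as sim

sites = pd.DataFrame({"contig": "chrS", "pos": np.arange(3000) * 3,
                      "strand": "+", "context": "CpG",
                      "m": 0.05, "h": 0.6})
bs = sim.simulate_pileups({}, sites, "BS", depth=10, seed=1)
ace = sim.simulate_pileups({}, sites, "ACE", depth=10, seed=2)
cd = sim.simulate_pileups({}, sites, "CD", depth=10, seed=3)

keep = ((bs.count_C + bs.count_T > 0) & (ace.count_C + ace.count_T > 0)
        & (cd.count_C + cd.count_T > 0)).to_numpy()
sub = pairing.subtraction_estimate(
    calling.raw_level(bs.count_C, bs.count_T)[keep],
    calling.raw_level(ace.count_C, ace.count_T)[keep])
direct = calling.raw_level(cd.count_C, cd.count_T)[keep]

print(f"true levels: m = 0.05, h = 0.60; depth 10x; {keep.sum()} sites")
print(f"subtraction estimator: mean {sub.mean():+.3f}, "
      f"sd {sub.std():.3f}, {100 * (sub < 0).mean():.1f}% negative")
print(f"direct CD-seq estimate: mean {direct.mean():+.3f}, "
      f"sd {direct.std():.3f}, 0.0% negative (bounded in [0, 1])")
print("\nThe negative fraction is pure artifact: a level cannot be "
      "negative.  Direct\ndetection removes it and roughly halves the "
      "estimator variance.")
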