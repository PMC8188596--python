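"""Compare acquisition utilities on one candidate's prediction.

For a candidate with predicted mean -8.5 and sd 0.5 (docking-score scale,
maximization convention: f = -score) and an incumbent f* = 8.2, each metric
trades exploitation against exploration differently.
"""

import numpy as np

from poolbo import AcquisitionConfig, utility

mu, var, f_star = 8.5, 0.25, 8.2
rng = np.random.default_rng(0)

print(f"candidate: mean {mu}, sd {var ** 0.5}; incumbent f* = {f_star}")
for metric in ("greedy", "ucb", "ei", "pi", "ts"):
    cfg = AcquisitionConfig(metric=metric, beta=2.0, xi=0.01)
    val = utility(metric, mu, var, f_star, cfg, rng)[0]
    print(f"  {metric:>6}: {val: .4f}")
# greedy is the mean itself; UCB adds beta*sd; EI is the expected margin
# over f*+xi (always >= 0); PI its probability (in [0,1]); TS one posterior
# draw, so it varies from run to run.
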