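"""Train the two surrogate architectures and inspect their uncertainties.

Fits a random forest (across-tree variance) and a NumPy feedforward net
(Monte-Carlo dropout) on 10% of a synthetic landscape, then measures how
well each ranks the unseen 90%.
"""

import numpy as np
from scipy.stats import spearmanr

import poolbo as pb

fx = pb.generate_pool(pb.LandscapeSpec(n_molecules=1500), seed=11)
rng = np.random.default_rng(0)
idx = rng.permutation(fx.pool.size)
tr, te = idx[:150], idx[150:]
data = pb.TrainingSet(fx.pool.fingerprints[tr], fx.true_objective[tr])

for arch in ("rf", "nn"):
    spec = pb.SurrogateSpec(architecture=arch)
    model = pb.train(spec, data, seed=1)
    pred = model.predict(fx.pool.fingerprints[te])
    rho = spearmanr(pred.mean, fx.true_objective[te]).statistic
    print(f"{arch}: uncertainty={spec.resolved_uncertainty:>17}  "
          f"held-out Spearman rho = {rho:.3f}  "
          f"mean predictive sd = {np.sqrt(pred.variance).mean():.3f}")
# rho near 1 means the surrogate ranks unseen molecules almost like the
# true landscape after seeing only 10% of it -- the property that lets
# model-guided acquisition skip most of the library.
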