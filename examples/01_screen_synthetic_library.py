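"""Screen a synthetic 2,000-molecule library with greedy RF optimization.

Generates a pool whose docking-style scores are a noisy linear function of
the molecules' atom-pair fingerprints, spends a 6% evaluation budget
(1% random init + five 1% greedy batches), and compares the top-k recovery
against a random search at the same budget, averaged over three seeds.
"""

import numpy as np

import poolbo as pb

N, K, SEEDS = 2000, 20, (3, 4, 5)

base = pb.generate_pool(pb.LandscapeSpec(n_molecules=N), seed=7)
sigma = 0.1 * pb.signal_sd(base)
fx = pb.generate_pool(pb.LandscapeSpec(n_molecules=N, noise_sigma=sigma), seed=7)
truth = pb.GroundTruth.from_lookup(fx.lookup)

means = {}
for metric in ("greedy", "random"):
    scores, ratios = [], []
    for seed in SEEDS:
        cfg = pb.ExplorerConfig(
            init_size=0.01, batch_size=0.01, max_iterations=5, k=K,
            surrogate=pb.SurrogateSpec(architecture="rf"),
            acquisition=pb.AcquisitionConfig(metric=metric),
            seed=seed,
        )
        rep = pb.run(fx.pool, fx.lookup, cfg)
        found = {r["smiles"]: r["objective"] for r in rep.explored}
        m = pb.report(found, truth, K)
        scores.append(m.scores_fraction)
        ratios.append(m.average_ratio)
    means[metric] = float(np.mean(scores))
    print(f"{metric:>7}: tested {rep.n_tested}/{N}  "
          f"top-{K} scores found {means[metric]:.0%}  "
          f"average ratio {np.mean(ratios):.3f}  (mean of {len(SEEDS)} seeds)")

if means["random"] > 0:
    ef = pb.enrichment_factor(means["greedy"], means["random"])
    print(f"enrichment factor over random search at equal budget: {ef:.1f}")
else:
    print("random baseline found no top-k scores; enrichment factor unbounded")
# scores fractions near 1 mean the model-guided search recovered almost the
# whole true top-k while docking only 6% of the library
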