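"""Stop exploring when the observed top-k average stops improving.

Runs the explorer with the dynamic convergence rule: terminate once the
fractional change of the current top-k average relative to the rolling mean
of the previous three iterations drops below 0.01.
"""

import poolbo as pb

fx = pb.generate_pool(pb.LandscapeSpec(n_molecules=1000), seed=5)

cfg = pb.ExplorerConfig(
    init_size=0.02, batch_size=0.02, max_iterations=15, k=10,
    stopping="converged", convergence_threshold=0.01, convergence_window=3,
    surrogate=pb.SurrogateSpec(architecture="rf"),
    seed=2,
)
rep = pb.run(fx.pool, fx.lookup, cfg)

for row in rep.log:
    print(f"iter {row['iteration']:>2}: tested {row['n_tested']:>3}  "
          f"top-{cfg.k} average {row['top_k_average']:.3f}")
print(f"converged: {rep.converged} after {rep.log[-1]['iteration']} iterations "
      f"({rep.n_tested / fx.pool.size:.0%} of the library)")
# the run halts as soon as three further batches stop moving the top-k
# average by more than 1%, instead of spending a fixed budget
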