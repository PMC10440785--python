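"""ML assembly versus maximum parsimony on the reduced shallow benchmark.

Simulates colonies (2 edit states, 20 recording units, depths 2-6), trains
the per-level classifiers on 200 colonies, reconstructs 30 held-out colonies
with both methods and compares the four scores.  Runs in about a minute.
"""

import lintracer as lt

cfg = lt.BenchmarkConfig(
    n_edit_states=2, n_units=20, n_train=200, n_test=30, seed=0,
)
out = lt.run_benchmark(cfg)

print(out["results"].groupby("method")[["rf", "trp", "qrt", "cli"]].mean().round(3))
imp = out["summary"]["improvement_pct"]
print(f"\nrelative RF improvement of ML over parsimony: {imp['rf']:.0f}%")
print("(positive = ML reconstructions are closer to the ground truth)")
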