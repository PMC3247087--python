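"""The two-stage detector on a 100-dimensional dataset hiding one XOR
pair: rank block matchings by joint QDA CV error, rescan the top
matchings pair by pair, and read off the hot spot."""

from qdadetect import (
    BlockSearchConfig,
    ScenarioSpec,
    add_noise_features,
    count_fits,
    detect_interactions,
    rank_block_matchings,
    simulate_scenario,
)

data = simulate_scenario(ScenarioSpec("xor", n0=40, n1=40, seed=7))
data = add_noise_features(data, 98, seed=7)  # signal = 2% of 100 features

config = BlockSearchConfig(bsize=5, p_star=10, top_m=6, seed=7)
blockwise, exhaustive = count_fits(data.n_features, config.bsize)
print(f"{data.n_features} features -> {blockwise} blockwise QDA fits "
      f"(vs {exhaustive} exhaustive)\n")

ranking = rank_block_matchings(data, config)
print("top 3 block matchings (block_a, block_b, joint CV error):")
for m in ranking.matchings[:3]:
    print(f"  blocks ({m.block_a:2d}, {m.block_b:2d})  error {m.cv_error:.3f}")

pairs = detect_interactions(data, config)
print("\nleading feature pairs after the stage-2 rescan:")
for r in pairs[:5]:
    print(
        f"  ({data.feature_ids[r.feature_i]}, {data.feature_ids[r.feature_j]})"
        f"  CV error {r.cv_error:.3f}  from matching rank {r.source_rank}"
    )

print(
    "\nThe planted (X1, X2) pair surfaces with a far lower pairwise error "
    "than any\nnoise pair; matchings of pure noise score near the 0.5 chance "
    "level."
)
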