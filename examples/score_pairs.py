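"""Compare the detector's criterion with the TSP and CorScor indexes:
each index sees only the pattern shape it assumes, while the QDA error
flags any pair the quadratic boundary can trace."""

from qdadetect import ScenarioSpec, cv_error, score_pairs, simulate_scenario

for scenario in ("linear", "xor"):
    data = simulate_scenario(ScenarioSpec(scenario, n0=40, n1=40, seed=1))
    scores = score_pairs(data, [(0, 1)]).iloc[0]
    qda = cv_error(data.X, data.y, seed=1).error_rate
    print(
        f"{scenario:7s} pair ({scores.feature_i}, {scores.feature_j}):  "
        f"TSP = {scores.tsp:.2f}   CorScor = {scores.corscor:.2f}   "
        f"QDA CV error = {qda:.3f}"
    )

print(
    "\nBoth pairs are strongly discriminative (low QDA error), yet each "
    "index misses one\nof them: the linear pattern leaves the within-class "
    "correlations identical (CorScor\nnear 0) and the XOR pattern keeps the "
    "within-class order relation symmetric (low\nTSP).  The QDA error is the "
    "wider-purpose criterion that flags both."
)
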