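"""Generate the four planted interaction patterns and show why their
single coordinates are useless while the pair classifies well."""

from qdadetect import SCENARIOS, ScenarioSpec, cv_errors_for_subsets, simulate_scenario

for scenario in SCENARIOS:
    data = simulate_scenario(ScenarioSpec(scenario, n0=40, n1=40, seed=0))
    errs, _, _ = cv_errors_for_subsets(data.X, data.y, [[0], [1], [0, 1]], seed=0)
    f1, f2 = data.feature_ids
    print(
        f"{scenario:9s}  CV error using {f1} alone: {errs[0]:.3f}   "
        f"{f2} alone: {errs[1]:.3f}   ({f1},{f2}) jointly: {errs[2]:.3f}"
    )

print(
    "\nEach coordinate alone misclassifies a quarter to a half of the "
    "samples (weak marginals);\nthe pair together drops the 10-fold CV "
    "QDA error to a few percent (strong bivariate signal)."
)
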