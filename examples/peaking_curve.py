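"""The peaking phenomenon: adding uninformative features at fixed
sample size degrades the designed classifier until the signal is lost."""

from qdadetect import PeakingConfig, ScenarioSpec, peaking_curve

config = PeakingConfig(
    scenario=ScenarioSpec("linear", n0=40, n1=40, seed=0),
    p_grid=[2, 5, 10, 15, 20, 30, 50, 100],
    B=10,
    seed=0,
)
print("dimension p   mean 10-fold CV QDA error (10 replicates)")
for p, err in peaking_curve(config):
    print(f"{p:11d}   {err:.3f}")

print(
    "\nAt p=2 the planted pair is nearly separable; by p=100 the 98 noise "
    "columns have\ndriven the plug-in QDA close to the 0.5 chance level — "
    "the peaking phenomenon."
)
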