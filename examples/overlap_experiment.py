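"""How far can QDA still tell a feature chunk hiding a signal from a
pure-noise chunk?  The Phi(-Delta/2) overlap between the two CV-error
populations answers this per dimension, and motivates the block-size
rule of the detector (2*bsize <= 10)."""

from qdadetect import PeakingConfig, ScenarioSpec, overlap_experiment

config = PeakingConfig(
    scenario=ScenarioSpec("xor", n0=40, n1=40, seed=0),
    p_grid=[2, 5, 10, 15, 20, 30],
    B=50,
    seed=0,
)
print("p    mean err (signal)  mean err (noise)  Delta   overlap Phi(-Delta/2)")
for res in overlap_experiment(config):
    print(
        f"{res.p:<4d} {res.errors_signal.mean():17.3f}"
        f"  {res.errors_noise.mean():16.3f}  {res.delta:5.2f}   {res.overlap:.4f}"
    )

print(
    "\nBelow p=10 the overlap is under 5%: a QDA error rate reliably flags "
    "which chunks\ncontain the signal.  As p grows the populations merge and "
    "the search would confuse\nsignal with noise — hence blocks small enough "
    "that a block-pair union stays under 10."
)
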