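"""Inject non-peptide decoy species from a NIST .msp library.

Decoys mimic chemical contaminants: each .msp entry gets a random retention
time and a lognormal abundance, elutes like any precursor and contributes
MS1 peaks (and MS2 fragments whenever its m/z falls in a DIA window).
"""

from pathlib import Path

from diasim import RunConfig, run_simulation

Path("decoys.msp").write_text(
    "Name: phthalate_like_contaminant\n"
    "PrecursorMZ: 447.3100\n"
    "Num Peaks: 3\n"
    "149.0233 100.0\n"
    "167.0339 30.0\n"
    "279.1591 12.0\n"
    "\n"
    "Name: peg_oligomer\n"
    "PrecursorMZ: 653.4200\n"
    "Num Peaks: 2\n"
    "133.0859 100.0\n"
    "177.1121 55.0\n"
)

config = RunConfig.resolve(overrides=dict(
    synthetic_n=30, seed=4, run_length=60.0, rt_padding=6.0,
    msp_path="decoys.msp",
))
result = run_simulation(config)

print(f"decoys loaded: {len(result.decoys)}")
for decoy in result.decoys:
    windows = [i for i, w in enumerate(result.schema.windows)
               if w.contains(decoy.precursor_mz)]
    print(f"  {decoy.name}: m/z {decoy.precursor_mz:.4f}, "
          f"RT {decoy.assigned_rt:.1f} s, abundance {decoy.base_abundance:.3g}, "
          f"DIA window {windows if windows else 'none (MS1 only)'}")
truth = result.truth
print("ground truth rows by source:",
      truth["source"].value_counts().to_dict())
# Decoy rows are flagged source=decoy in the ground truth, so downstream
# benchmarks can score identifications against them.
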