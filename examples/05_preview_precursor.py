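"""Preview a single precursor before committing to a full simulation.

Only the scans overlapping the selected precursor's elution are simulated,
so this runs in a fraction of the full-run time and is the quickest way to
sanity-check gradient, peak-shape and windowing settings.
"""

from diasim import RunConfig, preview
from diasim.library_io import generate_synthetic_library

records = generate_synthetic_library(50, seed=1)
target = records[0]

config = RunConfig.resolve(overrides=dict(
    synthetic_n=50, seed=1, run_length=300.0, rt_padding=15.0,
))
result = preview(config, f"{target.stripped_sequence}/{target.charge}")

print(result.summary)
print(f"simulated scans  : {len(result.xic_times)} MS1 points across the peak")
apex_ms1 = result.ms1_spectrum
print(f"MS1 at apex      : {len(apex_ms1.mz_array)} isotope peaks, "
      f"monoisotopic {apex_ms1.mz_array[0]:.4f} Th")
if result.ms2_spectrum is not None:
    print(f"MS2 at apex      : {len(result.ms2_spectrum.mz_array)} fragment peaks "
          f"in window {result.window_indices}")
# The apex RT equals the gradient mapping of the precursor's iRT exactly;
# expected PPP is the peak FWHM divided by the duty-cycle time.
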