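"""Generate a synthetic spectral library and inspect one precursor.

The generator produces tryptic-like peptides (7-20 residues, K/R terminus)
with exact monoisotopic precursor m/z, uniform iRT scores, lognormal
abundances and b/y fragment ladders — a stand-in for a Prosit library
export that needs no external data.
"""

from diasim.library_io import generate_synthetic_library, write_prosit_csv

records = generate_synthetic_library(100, seed=1)
write_prosit_csv(records, "synthetic_library.csv")

record = records[0]
print(f"library: {len(records)} precursors -> synthetic_library.csv")
print(f"example: {record.modified_sequence}/{record.charge}+")
print(f"  precursor m/z : {record.precursor_mz:.4f} Th")
print(f"  iRT           : {record.irt:.2f}")
print(f"  base abundance: {record.base_abundance:.3g}")
print(f"  fragments     : {len(record.fragments)} "
      f"(top: {record.fragments[0].series}{record.fragments[0].index} "
      f"at {record.fragments[0].mz:.4f} Th)")
# The m/z values are exact consequences of the peptide's elemental
# composition; everything downstream treats this library as ground truth.
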