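"""Fold a miRNA-style hairpin and read off the screening quantities.

Builds a mature + loop + star stem-loop, folds it with the internal
pair-energy model, and prints the dot-bracket structure, the minimum free
energy and the mature/star pairing count — the quantities novel-miRNA
screening thresholds operate on (MFE <= -18 kcal/mol, >= 14 pairs).
"""

from mircycle.annotate import revcomp
from mircycle.structure import fold_mfe

mature = "TGAGGTAGTAGGTTGTATAGTT"
loop = "TTCGTAGAACTT"
precursor = mature + loop + revcomp(mature)

fold = fold_mfe(precursor)
print(precursor)
print(fold.structure)
print(f"MFE = {fold.mfe:.1f} kcal/mol")

L = len(mature)
paired = sum(1 for i in range(L) if fold.pair_table.get(i, -1) >= L)
print(f"mature positions paired to the star arm: {paired}/{L}")
print(
    "\nAn MFE well below -18 kcal/mol and a fully paired mature arm are\n"
    "what a hairpin must show to be considered a credible precursor."
)
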