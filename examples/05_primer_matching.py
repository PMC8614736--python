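"""Degenerate-primer matching against a barcode region.

Checks whether the universal Folmer pair (LCO1490/HCO2198) and its
degenerate variant anneal to a target: a construct carrying the forward
site, a COI-like core, and the reverse-complemented reverse site, with a
couple of mutations to show the mismatch budget at work.
"""

import numpy as np

from barcodegap import load_folmer_primers, primer_match
from barcodegap.seqdelim import PrimerPair, reverse_complement

primers = load_folmer_primers()
folmer = PrimerPair(*primers.loc[primers.name == "folmer",
                                 ["forward", "reverse"]].iloc[0], "folmer")

rng = np.random.default_rng(1)
core = "".join(rng.choice(list("ACGT"), 600))
target = folmer.forward + core + reverse_complement(folmer.reverse)

# pristine target: both ends match exactly
res = primer_match(target, folmer, max_mismatch=3)
print(f"pristine target: found={res.found} "
      f"(fwd {res.forward.mismatches} mm at {res.forward.positions}, "
      f"rev {res.reverse.mismatches} mm)")

# mutate 2 positions in the forward site: still within the default budget
mutated = list(target)
mutated[2] = "C" if mutated[2] != "C" else "G"
mutated[10] = "C" if mutated[10] != "C" else "G"
res2 = primer_match("".join(mutated), folmer, max_mismatch=3)
print(f"2 mutations:     found={res2.found} "
      f"(fwd {res2.forward.mismatches} mm)")

# a degenerate primer's ambiguity codes absorb variation: instantiate its
# N/Y/R positions with random compatible bases and it still matches exactly
from barcodegap.seqdelim import match_primer
from barcodegap.tables_io import IUPAC_BASES

degen = primers.loc[primers.name == "folmer-degenerate",
                    "forward"].iloc[0]
instance = "".join(rng.choice(sorted(IUPAC_BASES[c])) for c in degen)
hit = match_primer("AAAA" + instance + "TTTT", degen, max_mismatch=0)
print(f"degenerate fwd vs a random instantiation of itself: "
      f"found={hit.found}, {hit.mismatches} mm at {hit.positions} "
      f"(IUPAC codes match when base sets intersect)")
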