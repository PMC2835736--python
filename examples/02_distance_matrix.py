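"""Log-corrected profile distances between sequences.

Builds a small alignment, prints the pairwise Jukes-Cantor-corrected
distance matrix, and shows the saturation cap at work.
"""

import sys

import profiletree as pt
from profiletree import profile_core

aln = pt.Alignment(
    names=["ref", "close", "far", "saturated"],
    rows=["ACGTACGTACGTACGT",
          "ACGTACGAACGTACGT",   # one mismatch in 16
          "ACCTGCGAATGTTCGA",   # several mismatches
          "TGCATGCATGCATGCA"],  # every position differs
    alphabet="nt")

M = pt.make_matrix(aln)
profile_core.write_phylip_matrix(aln.names, M, sys.stdout)
# Entries are -3/4 ln(1 - 4d/3) for mismatch fraction d, capped at 3.0
# substitutions/site: 1/16 mismatches -> 0.065; the all-different pair
# saturates at the cap.
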