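"""Predict an amplicon from a degenerate primer pair.

Plants the control-region primer pair 1,092 bases apart on a synthetic
reference and recovers the amplicon span; also shows that IUPAC codes in a
primer match either concrete base.
"""

import numpy as np

from haced.insilico_pcr import Primer, extract_amplicon, find_amplicons, iupac_match
from haced.seqio import SeqRecord, revcomp

fwd = Primer("ToCR3_F", "CAGGCTGAGCTGAGAACAAA")
rev = Primer("ToCR1_R", "GGGCCCATCTTAACATCTTCA")

rng = np.random.default_rng(0)
seq = list("".join(rng.choice(list("ACGT"), 2000)))
seq[100:120] = fwd.seq
rr = revcomp(rev.seq)
seq[1192 - len(rr):1192] = rr
ref = SeqRecord("synthetic_mtDNA", "".join(seq))

hits = find_amplicons(ref, fwd, rev, max_len=2000)
for hit in hits:
    amp = extract_amplicon(ref, hit)
    print(f"{hit.fwd_name}/{hit.rev_name}: [{hit.start}, {hit.end}) "
          f"-> {hit.length} bp amplicon")
    print(f"  starts with forward primer: {amp.startswith(fwd.seq)}")

print("Y matches C:", iupac_match("Y", "C"), "| Y matches A:", iupac_match("Y", "A"))

# One hit of 1,092 bases, spanning both primers inclusively; degenerate
# positions (Y = C/T, R = A/G) accept either base during the scan.
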