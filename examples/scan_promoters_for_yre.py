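"""Scan promoters for the Yap Response Element.

The YRE consensus 5'-T(T/G)A(C/G)T(C/A)A-3' is parsed from slash
notation into IUPAC classes (TKASTMA) and scanned over both strands of
simulated promoters: 90 motif-free backgrounds with the element planted
in 11 of them.
"""

from exoscreen import YRE, parse_slash_consensus, promoter_motif_fraction, scan_sequence
from exoscreen.simulate import simulate_promoters

pattern = parse_slash_consensus("TT/GAC/GTC/AA", name="YRE")
print(f"consensus TT/GAC/GTC/AA parsed as IUPAC {pattern.iupac}")

for probe in ("TTACTAA", "TGACTCA", "TTTTTTT"):
    hits = scan_sequence(probe, pattern, both_strands=False)
    print(f"  {probe}: {'match' if hits else 'no match'}")

genes = [f"gene{i:03d}" for i in range(90)]
planted = {g: -400 for g in genes[:11]}  # plant 400 bp upstream of the TSS
promoters, truth = simulate_promoters(genes, YRE, planted, length=600, seed=42)
n_with, fraction = promoter_motif_fraction(set(genes), promoters, YRE)
print(f"promoters with a YRE: {n_with} of {len(genes)} ({fraction:.1%})")

# The planted promoters and only those carry the element, so the
# gene-level fraction reproduces the planted 11/90.
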