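"""Annotate E-box motifs in a promoter-like sequence.

MYC-family factors bind the palindromic 6-mer E-box: canonical CACGTG and
non-canonical CANNTG variants (e.g. CACCTG, CAGCTG).  Because both patterns
are reverse-complement palindromic as patterns, a single-strand scan finds
every site.
"""

from nbscreen import ebox_scan

promoter = (
    "GGCTATCACGTGTTAGCCAATCAGCTGACGTTTCCACCTGAAGGCTTACACGTGGT"
    "TCCGGACATTTGCCAATGGTACGCGTAGCT"
)

hits = ebox_scan(promoter)
print(f"sequence length {len(promoter)} nt, {len(hits)} E-box hits\n")
for h in hits:
    print(f"  position {h.position:3d}  {h.sequence}  {h.kind}")

n_canon = sum(h.kind == "canonical" for h in hits)
print(
    f"\n{n_canon} canonical (CACGTG) and {len(hits) - n_canon} non-canonical "
    f"(CANNTG) sites.\nCanonical sites are the high-affinity MYC-family "
    f"binding motif; non-canonical\nsites are weaker but common in bound "
    f"promoters."
)
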