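"""Derive the four canonical seed-site words of a miRNA and scan a UTR.

The seed (miRNA nt 2-8) defines four match classes on the mRNA:
8mer > 7mer-m8 > 7mer-1A > 6mer.  Overlapping matches at one position
collapse to the strongest class.
"""

from ripuse import MIR100_5P, MIR125B_5P, scan_sites, best_site_type

for mi in (MIR100_5P, MIR125B_5P):
    print(f"{mi.name}  mature 5'->3': {mi.mature_seq}")
    for st, word in mi.site_words().items():
        print(f"  {st.label:8s} -> {word}")

utr = "CCAATACGGGTAAACCACGGGTCC"
print(f"\nscanning {utr!r} for {MIR100_5P.name} sites:")
for a in scan_sites(utr, MIR100_5P, "demo"):
    print(f"  [{a.start},{a.end})  {a.site_type.label:8s} {a.word}")
print("best site class:", best_site_type(utr, MIR100_5P).label)
# The 8mer at position 3 is reported once (not also as its embedded 7mers),
# while the separate 6mer downstream is reported independently.
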