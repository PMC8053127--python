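"""Browse the bundled Arabidopsis Nm annotation tables.

The package ships the printed 2'-O-methylation maps for Arabidopsis
cytoplasmic rRNAs (111 sites), chloroplast/mitochondrial rRNAs (5 + 5) and
spliceosomal snRNAs (19), with guide snoRNA assignments and non-canonical
targeting flags.
"""

from collections import Counter

import ribometh as rm

cyt = rm.cytoplasmic_nm_sites()
print("cytoplasmic rRNA Nm:", len(cyt), dict(Counter(s.rna_id for s in cyt)))
noncanon = [s.label for s in cyt if s.noncanonical]
print("non-canonical (D'+6 / D'+7) targets:", ", ".join(noncanon))

org = rm.organellar_nm_sites()
print("organellar Nm:", [(s.rna_id, f"{s.base}{s.position}") for s in org])

snr = rm.snrna_nm_sites()
print("snRNA Nm per snRNA:", dict(Counter(s.rna_id for s in snr)))

# conservation intersection with an identity coordinate map
venn = rm.conservation_intersect({
    "setA": cyt[:10], "setB": cyt[5:15],
})[1]
print("toy conservation Venn over 15 sites:",
      {"A only": venn.get(frozenset({"setA"}), 0),
       "shared": venn.get(frozenset({"setA", "setB"}), 0),
       "B only": venn.get(frozenset({"setB"}), 0)})
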