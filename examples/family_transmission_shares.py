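"""Transmission shares of one family, coreplicon by coreplicon.

A diploid XY mated pair has two daughters and one son.  Each parent's share
of each whole offspring is counted per parental haploid set and weighted by
genetic contribution, so the same family yields different share arrays at
autosomes, the X, the Y, and the mitochondrion.  Ploidy-weighted parental
shares of every gene-carrying offspring sum to exactly 1.
"""

from rvfitness import family_shares, make_xy_family

families = make_xy_family()
for coreplicon in ("autosome", "X", "Y", "mitochondrial"):
    shares = family_shares(families[coreplicon])
    print(f"{coreplicon}:")
    for parent in ("mother", "father"):
        d = shares[parent].as_dict()
        pretty = {f"{cls}": str(v) for (cls, _), v in d.items()} or "no shares"
        print(f"  {parent:6s} -> {pretty}")

print()
print("Reading: at autosomes each parent holds 1/2 of each daughter and 1/4")
print("of the son per haploid set; at the X the haploid father holds each")
print("daughter whole (share 1) and none of the son, who got his X from his")
print("mother (share 1/2 per maternal haploid set).")
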