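"""Classify a query that sits between two congeneric species.

Builds a three-species toy database in memory (two Lactobacillus species
~4% apart plus an unrelated outgroup), then classifies a read derived from
L. acidophilus with a little sequencing noise.  Expected outcome: confident
assignment down to species, because the read is much closer to one congener
than the other; the outgroup never survives the hit filters.
"""

import numpy as np

from bayeslca import QueryRecord, ReferenceRecord, TaxonomyTree, classify_query
from bayeslca.simulate import mutate_read

rng = np.random.default_rng(0)

tree = TaxonomyTree({
    "root": ("root", "no rank", None),
    "k1": ("Bacteria", "superkingdom", "root"),
    "p1": ("Firmicutes", "phylum", "k1"),
    "c1": ("Bacilli", "class", "p1"),
    "o1": ("Lactobacillales", "order", "c1"),
    "f1": ("Lactobacillaceae", "family", "o1"),
    "g1": ("Lactobacillus", "genus", "f1"),
    "s1": ("Lactobacillus acidophilus", "species", "g1"),
    "s2": ("Lactobacillus casei", "species", "g1"),
    "p2": ("Proteobacteria", "phylum", "k1"),
    "c2": ("Gammaproteobacteria", "class", "p2"),
    "o2": ("Enterobacterales", "order", "c2"),
    "f2": ("Enterobacteriaceae", "family", "o2"),
    "g2": ("Escherichia", "genus", "f2"),
    "s3": ("Escherichia coli", "species", "g2"),
})

acidophilus = "".join(rng.choice(list("ACGT"), size=500))
casei = mutate_read(acidophilus, 0.04, rng)       # congener, ~4% diverged
coli = "".join(rng.choice(list("ACGT"), size=500))  # unrelated outgroup

references = {
    "r_acid": ReferenceRecord("r_acid", acidophilus, "s1"),
    "r_casei": ReferenceRecord("r_casei", casei, "s2"),
    "r_coli": ReferenceRecord("r_coli", coli, "s3"),
}

read = QueryRecord(id="read1", seq=mutate_read(acidophilus, 0.01, rng))
row = classify_query(read, references, tree, confidence_threshold=0.8,
                     rng=np.random.default_rng(1))

print(f"query {row.query_id}:")
for a in row.assignments:
    conf = "" if a.confidence is None else f"  (confidence {a.confidence:.2f})"
    print(f"  {a.rank:>12}: {a.name}{conf}")
print("\nEach rank is assigned its top-bootstrap-confidence taxon, reported")
print("only when the confidence reaches the threshold (0.8 here).")
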