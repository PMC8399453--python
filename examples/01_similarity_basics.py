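"""Angular cosine similarity between patent keyword vectors.

Each patent is reduced to its top-M most frequent cleaned lemmas; the
similarity coefficient c = (2/pi)*arccos(cos(v_i, v_j)) is 0 for
coinciding keyword lists, 1 for disjoint ones, and in between otherwise.
"""

from patentscape import PatentVector, similarity

a = PatentVector("A", [("complex", 4), ("water", 2), ("solution", 1)])
b = PatentVector("B", [("complex", 4), ("water", 2), ("solution", 1)])
c = PatentVector("C", [("gel", 3), ("patch", 1), ("fiber", 1)])
d = PatentVector("D", [("complex", 1), ("gel", 1)])

print(f"identical lists   c(A,B) = {similarity(a, b):.4f}   (maximally similar)")
print(f"disjoint lists    c(A,C) = {similarity(a, c):.4f}   (nothing in common)")
print(f"partial overlap   c(A,D) = {similarity(a, d):.4f}   (shares 'complex' only)")
# c is a normalized angle: 0.7 means the two keyword profiles are 63
# degrees apart out of the maximum 90 reachable with count vectors.
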