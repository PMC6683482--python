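"""Segregation analysis: genotype probabilities from partial genotyping.

A sire is a known carrier of a lethal recessive allele; none of his progeny
are genotyped.  Peeling propagates the information down (each progeny has an
elevated carrier probability) and back up (an affected calf would implicate
both parents).
"""

from lofmate.pedigree import build_pedigree
from lofmate.segprob import genotype_probabilities

rows = [
    {"id": "SIRE", "sire": "0", "dam": "0", "sex": "M", "role": "ancestor"},
    {"id": "DAM1", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    {"id": "DAM2", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    {"id": "CALF1", "sire": "SIRE", "dam": "DAM1", "sex": "M", "role": "candidate"},
    {"id": "CALF2", "sire": "SIRE", "dam": "DAM1", "sex": "F", "role": "candidate"},
    {"id": "CALF3", "sire": "SIRE", "dam": "DAM2", "sex": "F", "role": "candidate"},
]
ped = build_pedigree(rows)
q = 0.05  # population lethal-allele frequency

print(f"Allele frequency q = {q}; Hardy-Weinberg carrier rate = {2*q*(1-q):.4f}")
print()
print("Only the sire genotyped, found to be a carrier (Aa):")
post = genotype_probabilities(ped, {"SIRE": 1}, q=q)
print(post.round(4))
print()
print("Each calf's carrier probability rises to ~0.5 (half the sire's "
      "gametes carry the allele; the dam contributes only the prior).")
print()

print("Now CALF1 is also genotyped and is a carrier:")
post2 = genotype_probabilities(ped, {"SIRE": 1, "CALF1": 1}, q=q)
print(post2.round(4))
print()
print("DAM1's carrier probability moved only slightly: the sire already "
      "explains CALF1's allele.  Information flows both down and up the "
      "pedigree (and through loops, when the pedigree has them).")
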