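"""Kinship and parental coancestry on a small worked pedigree.

Builds a three-generation pedigree by hand, computes the full kinship matrix
with the tabular method, and shows how a mating list's parental coancestry
(x'Kx in parent-contribution proportions) responds to concentrating versus
spreading sire usage.
"""

from lofmate.pedigree import build_pedigree, kinship_matrix, parental_coancestry

rows = [
    {"id": "GS", "sire": "0", "dam": "0", "sex": "M", "role": "ancestor"},
    {"id": "GD", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    {"id": "S1", "sire": "GS", "dam": "GD", "sex": "M", "role": "ancestor"},
    {"id": "S2", "sire": "GS", "dam": "GD", "sex": "M", "role": "ancestor"},
    {"id": "D1", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    {"id": "D2", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    {"id": "A", "sire": "S1", "dam": "D1", "sex": "M", "role": "candidate"},
    {"id": "B", "sire": "S2", "dam": "D2", "sex": "M", "role": "candidate"},
    {"id": "C", "sire": "S1", "dam": "D2", "sex": "F", "role": "candidate"},
    {"id": "D", "sire": "S2", "dam": "D1", "sex": "F", "role": "candidate"},
]
ped = build_pedigree(rows)
K = kinship_matrix(ped)

print("Kinship among the four candidates (A, B are half-cousins of C, D):")
print(K.loc[["A", "B", "C", "D"], ["A", "B", "C", "D"]].round(4))
print()

concentrated = [("A", "C"), ("A", "D")]  # one sire covers both dams
spread = [("A", "C"), ("B", "D")]  # usage split over two sires
print(f"coancestry, one sire used twice: "
      f"{parental_coancestry(ped, K, concentrated):.4f}")
print(f"coancestry, two sires used once: "
      f"{parental_coancestry(ped, K, spread):.4f}")
print("Spreading usage lowers x'Kx, the quantity the 25-degree compromise "
      "trades against index gain.")
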