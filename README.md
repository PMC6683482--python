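# lofmate

Mate selection and economics of lethal recessive alleles in beef herds.

Recessive loss-of-function (LOF) alleles are individually rare but
collectively common in cattle populations; matings between carriers lose ¼ of
conceptions to embryonic death. `lofmate` implements the full decision
pipeline for managing them within a single breeding cycle:

1. **Pedigree & kinship** — tabular kinship, inbreeding, and the parental
   coancestry `x'Kx` of a mating list (`lofmate.pedigree`).
2. **Synthetic herd** — pedigree, 7-trait EPDs, and lethal-locus panels
   (scenarios A/B/C: 7 high-frequency, 76 low-frequency, 50 mixed loci)
   shaped like the study herd (`lofmate.synth`).
3. **Gene dropping** — founder haplotypes from a burned-in population,
   Mendelian transmission down the pedigree, lethal homozygotes rejected
   (`lofmate.genedrop`).
4. **Selection index** — index coefficients from the genetic parameters, $M
   per animal, mid-parent progeny index, $MB (`lofmate.index`).
5. **Segregation analysis** — exact junction-tree peeling (loopy-BP fallback)
   turns partial genotyping into per-animal carrier probabilities
   (`lofmate.segprob`).
6. **Lethality metrics** — LethalG (progeny mortality of the list), LethalA
   (grandprogeny mortality), and the sire genetic load score
   (`lofmate.lethal`).
7. **Mate selection** — an evolutionary algorithm places the mating list at a
   target angle on the index-vs-coancestry frontier while penalizing
   lethality (`lofmate.matesel`).
8. **Economics & experiments** — $P per mating, genotyping savings and
   breakeven test values, and the scenario × strategy × weighting × tier
   study driver (`lofmate.econ`, `lofmate.experiments`).

## Worked example

A sire is a known carrier; peeling spreads that information through the
pedigree:

```python
from lofmate.pedigree import build_pedigree
from lofmate.segprob import genotype_probabilities

ped = build_pedigree([
    {"id": "SIRE",  "sire": "0",    "dam": "0",    "sex": "M", "role": "ancestor"},
    {"id": "DAM1",  "sire": "0",    "dam": "0",    "sex": "F", "role": "ancestor"},
    {"id": "CALF1", "sire": "SIRE", "dam": "DAM1", "sex": "M", "role": "candidate"},
])
print(genotype_probabilities(ped, {"SIRE": 1}, q=0.05).round(4))
```

```
          pAA    pAa     paa
id
SIRE   0.0000  1.000  0.0000
DAM1   0.9025  0.095  0.0025
CALF1  0.4750  0.500  0.0250
```

Feeding such probabilities into the optimizer re-pairs carriers at almost no
index cost (`examples/03_mate_selection.py`, full genotyping, 15 matings):

```
no lethality penalty:
  mean progeny index       0.24
  LethalG                0.0667  (6.67 affected per 100 matings)
heavy LethalG penalty (wG = 100):
  mean progeny index       0.23
  LethalG                0.0000  (0.00 affected per 100 matings)
```

The `examples/` directory walks through each stage:

| script | shows |
|---|---|
| `01_kinship_and_coancestry.py` | kinship matrix; spreading sire usage lowers `x'Kx` |
| `02_genotype_probabilities.py` | peeling with partial genotyping |
| `03_mate_selection.py` | penalized mate selection on a synthetic herd |
| `04_genotyping_economics.py` | $P, savings, net profit, breakeven test value |
| `05_mini_study.py` | end-to-end sweep: more genotyping → fewer affected, higher $P |

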