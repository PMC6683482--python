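"""Lethality metrics for a mating list: LethalG, LethalA and the sire GLS.

All three consume per-animal, per-locus genotype-probability triples
(P_AA, P_Aa, P_aa) — point genotypes are the special case of unit masses —
plus the panel of lethal-allele frequencies.

* ``lethal_g``: probability that a progeny of the list dies from
  homozygosity at any loss-of-function locus (the short-term criterion).
* ``lethal_a``: probability that a *grandprogeny* dies, given random mating
  of the surviving progeny at the current candidate allele frequencies (the
  long-term criterion, which discriminates against carrier parents
  regardless of the mates they receive).
* ``genetic_load_score``: mating-weighted sum over sires of q^2 at each
  locus where the sire is heterozygous, divided by the number of matings.

Loci are treated as independent; multi-locus mortality combines per-locus
death probabilities as the complement of a product (a union of independent
events), which keeps every metric a probability.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "transmission_prob",
    "pair_mortality",
    "lethal_g",
    "lethal_a",
    "genetic_load_score",
]


def _as_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("genotype probabilities must have a trailing axis of 3")
    if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("genotype probability triples must sum to 1")
    return p


def transmission_prob(probs: np.ndarray) -> np.ndarray:
    """P(parent transmits a) per locus: P_Aa / 2 + P_aa."""
    p = _as_probs(probs)
    return 0.5 * p[..., 1] + p[..., 2]


def pair_mortality(probs_sire: np.ndarray, probs_dam: np.ndarray) -> float:
    """Probability a progeny of this pair is aa at one or more loci.

    Per locus, P(aa) = a_s * a_d where a_p is the parent's marginal
    probability of transmitting the lethal allele (the sum over parental
    genotype pairs of P(g_s) P(g_d) Mendel(aa | g_s, g_d) factorizes because
    the two transmissions are independent).  Loci combine as
    1 - prod_l (1 - p_l).
    """
    p_l = transmission_prob(probs_sire) * transmission_prob(probs_dam)
    return float(1.0 - np.prod(1.0 - p_l))


def _pair_transmissions(
    matings: list[tuple[str, str]], probs: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """(n_matings, n_loci) lethal-transmission probabilities for sires, dams."""
    if len(matings) == 0:
        raise ValueError("empty mating list")
    a_s = np.stack([transmission_prob(probs[s]) for s, _ in matings])
    a_d = np.stack([transmission_prob(probs[d]) for _, d in matings])
    return a_s, a_d


def lethal_g(matings: list[tuple[str, str]], probs: dict[str, np.ndarray]) -> float:
    """Mean pair mortality over the mating list.

    Multiplying by 100 gives the expected number of affected (aa) conceptions
    per 100 matings.
    """
    a_s, a_d = _pair_transmissions(matings, probs)
    p = a_s * a_d
    return float(np.mean(1.0 - np.prod(1.0 - p, axis=1)))


def lethal_a(
    matings: list[tuple[str, str]],
    probs: dict[str, np.ndarray],
    q: np.ndarray,
    survivor_condition: bool = True,
) -> float:
    """Grandprogeny mortality under random mating of the surviving progeny.

    For each mating and locus, the probability t that a surviving progeny
    transmits the lethal allele is half its carrier probability; with
    ``survivor_condition`` (default) the progeny genotype distribution is
    conditioned on not being aa (dead progeny cannot breed), otherwise the
    unconditional distribution is used, in which case t = (a_s + a_d) / 2 and
    the metric depends only on which parents are used, not on the pairings.
    The cohort transmission frequency t_bar (mean over matings) meets a mate
    drawn at the current candidate frequency q_l, and loci combine as
    1 - prod_l (1 - t_bar_l * q_l).
    """
    q = np.asarray(q, dtype=float)
    a_s, a_d = _pair_transmissions(matings, probs)
    p_aa = a_s * a_d
    p_carrier = a_s * (1 - a_d) + a_d * (1 - a_s)
    if survivor_condition:
        with np.errstate(invalid="ignore"):
            t = np.where(p_aa < 1.0, 0.5 * p_carrier / (1.0 - p_aa), 0.0)
    else:
        t = 0.5 * p_carrier + p_aa  # = (a_s + a_d) / 2
    t_bar = t.mean(axis=0)
    return float(1.0 - np.prod(1.0 - t_bar * q))


def genetic_load_score(
    matings: list[tuple[str, str]],
    probs: dict[str, np.ndarray],
    q: np.ndarray,
) -> float:
    """GLS = sum_s n_s * sum_l P(sire s is Aa at l) q_l^2 / N_matings."""
    if len(matings) == 0:
        raise ValueError("empty mating list")
    q2 = np.asarray(q, dtype=float) ** 2
    counts: dict[str, int] = {}
    for s, _ in matings:
        counts[s] = counts.get(s, 0) + 1
    total = 0.0
    for s, n_s in counts.items():
        p_het = _as_probs(probs[s])[..., 1]
        total += n_s * float(np.dot(p_het, q2))
    return total / len(matings)
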