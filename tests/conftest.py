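"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: genotype
posteriors come from materializing the full joint distribution over all
animals, and kinship comes from enumerating every gamete-inheritance pattern
in the pedigree.  Both are exponential-time and only usable on tiny
pedigrees, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from lofmate.pedigree import Pedigree, build_pedigree

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def point_probs(genotypes) -> np.ndarray:
    """Unit-mass probability triples from genotype codes (per locus)."""
    g = np.atleast_1d(np.asarray(genotypes, dtype=int))
    out = np.zeros((len(g), 3))
    out[np.arange(len(g)), g] = 1.0
    return out


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return build_pedigree(
        [
            {"id": "S", "sire": "0", "dam": "0", "sex": "M", "role": "ancestor"},
            {"id": "D", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
            {"id": "C", "sire": "S", "dam": "D", "sex": "M", "role": "candidate"},
        ]
    )


def random_pedigree(rng: np.random.Generator, n: int, founder_prob: float = 0.25) -> Pedigree:
    """Random pedigree with shared mates and inbreeding loops."""
    rows = [
        {"id": "m0", "sire": "0", "dam": "0", "sex": "M", "role": "ancestor"},
        {"id": "f0", "sire": "0", "dam": "0", "sex": "F", "role": "ancestor"},
    ]
    for k in range(2, n):
        males = [r["id"] for r in rows if r["sex"] == "M"]
        females = [r["id"] for r in rows if r["sex"] == "F"]
        if rng.random() < founder_prob:
            sire = dam = "0"
        else:
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
        rows.append(
            {
                "id": f"x{k}",
                "sire": sire,
                "dam": dam,
                "sex": "M" if rng.random() < 0.5 else "F",
                "role": "candidate",
            }
        )
    return build_pedigree(rows)


# ---------------------------------------------------------------------------
# full-joint genotype oracle


def _expand(table: np.ndarray, vars_: tuple[int, ...], n: int) -> np.ndarray:
    shape = list(table.shape) + [1] * (n - len(vars_))
    return np.moveaxis(table.reshape(shape), range(len(vars_)), vars_)


def joint_genotype_marginals(
    ped: Pedigree,
    q: float,
    observed: dict[str, int],
    condition_alive: bool = False,
) -> np.ndarray:
    """Posterior genotype marginals by summing the explicit joint over 3^n states."""
    n = len(ped)
    assert n <= 13, "joint oracle is exponential in herd size"
    par = ped.parent_indices()
    trans = np.array([0.0, 0.5, 1.0])
    prior = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    child = np.stack(
        [
            (1 - trans[:, None]) * (1 - trans[None, :]),
            trans[:, None] * (1 - trans[None, :]) + trans[None, :] * (1 - trans[:, None]),
            trans[:, None] * trans[None, :],
        ]
    )  # (child, sire, dam)
    joint = np.ones((3,) * n)
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            joint = joint * _expand(prior, (i,), n)
        elif s >= 0 and d >= 0:
            joint = joint * _expand(child, (i, s, d), n)
        else:
            k = s if s >= 0 else d
            joint = joint * _expand(np.einsum("csd,d->cs", child, prior), (i, k), n)
    for a, g in observed.items():
        e = np.zeros(3)
        e[g] = 1.0
        joint = joint * _expand(e, (ped.index_of(a),), n)
    if condition_alive:
        alive = np.array([1.0, 1.0, 0.0])
        for i in range(n):
            if ped.ids[i] not in observed:
                joint = joint * _expand(alive, (i,), n)
    marg = np.zeros((n, 3))
    for i in range(n):
        m = joint.sum(axis=tuple(j for j in range(n) if j != i))
        marg[i] = m / m.sum()
    return marg


# ---------------------------------------------------------------------------
# inheritance-pattern kinship oracle


def kinship_by_gamete_enumeration(ped: Pedigree) -> np.ndarray:
    """Exact kinship by averaging allele identity over all inheritance patterns.

    Founders get unique allele labels; every non-founder gamete picks one of
    its parent's two alleles, and all 2^(2k) inheritance patterns over the k
    non-founders are enumerated.  kinship(i, j) is the probability that one
    random allele from i and one from j are identical by descent.
    """
    n = len(ped)
    par = ped.parent_indices()
    nonfounders = [i for i in range(n) if par[i][0] >= 0 or par[i][1] >= 0]
    k = len(nonfounders)
    assert 2 * k <= 20, "gamete enumeration oracle is exponential"
    kin = np.zeros((n, n))
    n_pat = 2 ** (2 * k)
    next_allele = 0
    founder_alleles = {}
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            founder_alleles[i] = (next_allele, next_allele + 1)
            next_allele += 2
    # alleles for a founder-parent slot of a non-founder with one unknown parent
    unknown_slots = {}
    for i in nonfounders:
        for slot, p in enumerate(par[i]):
            if p < 0:
                unknown_slots[(i, slot)] = (next_allele, next_allele + 1)
                next_allele += 2
    for pattern in range(n_pat):
        alleles = np.zeros((n, 2), dtype=int)
        for i, fa in founder_alleles.items():
            alleles[i] = fa
        for pos, i in enumerate(nonfounders):  # pedigree order: parents first
            for slot, p in enumerate(par[i]):
                bit = (pattern >> (2 * pos + slot)) & 1
                if p >= 0:
                    alleles[i, slot] = alleles[p, bit]
                else:
                    alleles[i, slot] = unknown_slots[(i, slot)][bit]
        eq = alleles[:, :, None, None] == alleles[None, None, :, :]
        # probability a random allele from i matches a random allele from j
        kin += eq.transpose(0, 2, 1, 3).reshape(n, n, 4).mean(axis=2)
    return kin / n_pat
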