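"""Gene dropping of lethal recessive loci through a pedigree.

Founder genotypes are created by iterating a random-union-of-gametes
population (burn-in) with recombination on a bovine-sized genome map and
mutation, then pinning terminal allele frequencies back to the panel targets.
Alleles are then dropped through the pedigree by Mendelian segregation.  At
every stage, homozygous recessive (aa) individuals at any loss-of-function
locus are embryonic-lethal: they are rejected and redrawn, because a recorded
pedigree contains only survivors.

Genotypes are coded as the count of the lethal allele a: 0 = AA, 1 = Aa,
2 = aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .synth import LocusPanel

__all__ = [
    "GenomeMap",
    "FounderPool",
    "GenotypeState",
    "kosambi",
    "burn_in_founders",
    "drop_genotypes",
    "sample_offspring_locus",
]

GENOTYPE_LABELS = np.array(["AA", "Aa", "aa"])


def kosambi(d) -> np.ndarray | float:
    """Kosambi map function: recombination fraction for map distance d (Morgans).

    r(d) = tanh(2 d) / 2, so r(0) = 0 and r -> 0.5 as d -> infinity.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d)
    return float(r) if r.ndim == 0 else r


@dataclass
class GenomeMap:
    """Locus placement on a bovine-sized genome.

    Defaults: 29 autosomes totalling 3 Gb, converted to map length at
    1 cM/Mb (30 Morgans total), Kosambi mapping, and a mutation rate of
    2.2e-9 per site per generation.
    """

    n_chromosomes: int = 29
    genome_size_bp: float = 3.0e9
    cm_per_mb: float = 1.0
    mutation_rate: float = 2.2e-9
    chromosome: np.ndarray | None = None  # per-locus chromosome index
    position_m: np.ndarray | None = None  # per-locus position in Morgans

    @property
    def chromosome_length_m(self) -> float:
        return (self.genome_size_bp / self.n_chromosomes) / 1e6 * self.cm_per_mb / 100.0

    @classmethod
    def random(cls, n_loci: int, seed: int, **kwargs) -> "GenomeMap":
        """Scatter ``n_loci`` uniformly over the genome (sorted within chromosome)."""
        gmap = cls(**kwargs)
        rng = np.random.default_rng(seed)
        chrom = np.sort(rng.integers(0, gmap.n_chromosomes, size=n_loci))
        pos = rng.uniform(0.0, gmap.chromosome_length_m, size=n_loci)
        order = np.lexsort((pos, chrom))
        gmap.chromosome = chrom[order]
        gmap.position_m = pos[order]
        return gmap

    def adjacent_recombination(self) -> np.ndarray:
        """Recombination fraction between consecutive loci (0.5 across chromosomes)."""
        if self.chromosome is None or self.position_m is None:
            raise ValueError("loci have not been placed on the map")
        d = np.diff(self.position_m)
        r = kosambi(np.abs(d))
        r = np.where(np.diff(self.chromosome) != 0, 0.5, r)
        return np.asarray(r, dtype=float)


@dataclass
class FounderPool:
    """Diploid individuals available to seed pedigree founders.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with entries in {0, 1}
    (1 = lethal allele); no individual is aa at any locus.
    """

    haplotypes: np.ndarray
    panel: LocusPanel

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class GenotypeState:
    """Per animal x locus genotypes (allele-a counts), aligned to pedigree order."""

    genotypes: np.ndarray  # (n_animals, n_loci) int8 in {0, 1, 2}
    ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.ids)}

    def of(self, animal_id: str) -> np.ndarray:
        return self.genotypes[self._index[animal_id]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format ``id,locus,genotype`` table with AA/Aa/aa labels."""
        n, L = self.genotypes.shape
        return pd.DataFrame(
            {
                "id": np.repeat(self.ids, L),
                "locus": np.tile([f"L{j:03d}" for j in range(L)], n),
                "genotype": GENOTYPE_LABELS[self.genotypes.ravel()],
            }
        )

    def allele_frequencies(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0


def _gametes(hap: np.ndarray, parents: np.ndarray, r_adj: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per row of ``parents`` from haplotype array ``hap``.

    ``hap`` is (n_ind, 2, L); crossover pattern: the source haplotype switches
    between adjacent loci with the mapped recombination fraction.
    """
    n = len(parents)
    L = hap.shape[2]
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        switches = rng.random((n, L - 1)) < r_adj
        idx = (start + np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
        )) % 2
    else:
        idx = start
    return np.take_along_axis(hap[parents], idx[:, None, :], axis=1)[:, 0, :]


def burn_in_founders(
    panel: LocusPanel,
    gmap: GenomeMap,
    n_pop: int = 500,
    n_generations: int = 1000,
    seed: int = 0,
    max_rejection_rounds: int = 200,
    pin_tolerance: float = 0.01,
) -> FounderPool:
    """Create a founder gene pool by iterated random mating with lethality.

    The population starts at the panel's target frequencies (HWE, aa
    rejected), then iterates ``n_generations`` of random union of gametes with
    recombination (Kosambi map) and symmetric mutation at ``gmap.mutation_rate``,
    rejecting aa individuals each generation.  Because drift (and the
    selection implied by rejection) moves frequencies off target over a long
    burn-in, terminal frequencies are pinned back to the panel values by
    editing randomly chosen haplotypes (never creating an aa individual); the
    pool is only returned once every locus is within ``pin_tolerance`` of its
    target.
    """
    if n_pop < 50:
        raise ValueError("burn-in population must have at least 50 individuals")
    if gmap.chromosome is None:
        raise ValueError("genome map has no locus placements")
    q = panel.frequencies
    L = len(q)
    rng = np.random.default_rng(seed)
    r_adj = gmap.adjacent_recombination() if L > 1 else np.empty(0)

    hap = (rng.random((n_pop, 2, L)) < q[None, None, :]).astype(np.int8)
    _reject_redraw_initial(hap, q, rng)

    mu = gmap.mutation_rate
    for _ in range(n_generations):
        sires = rng.integers(0, n_pop, size=n_pop)
        dams = rng.integers(0, n_pop, size=n_pop)
        child = np.stack(
            [_gametes(hap, sires, r_adj, rng), _gametes(hap, dams, r_adj, rng)], axis=1
        )
        if mu > 0:
            flips = rng.random(child.shape) < mu
            child ^= flips.astype(np.int8)
        # lethality: redraw aa individuals from new random parents
        for _ in range(max_rejection_rounds):
            dead = (child.sum(axis=1) == 2).any(axis=1)
            if not dead.any():
                break
            k = int(dead.sum())
            rs = rng.integers(0, n_pop, size=k)
            rd = rng.integers(0, n_pop, size=k)
            child[dead] = np.stack(
                [_gametes(hap, rs, r_adj, rng), _gametes(hap, rd, r_adj, rng)], axis=1
            )
        else:
            raise RuntimeError("could not produce a lethal-free generation")
        hap = child

    _pin_frequencies(hap, q, rng)
    realized = hap.mean(axis=(0, 1))
    if np.any(np.abs(realized - q) > pin_tolerance):
        raise RuntimeError("failed to pin founder frequencies to panel targets")
    return FounderPool(haplotypes=hap, panel=panel)


def _reject_redraw_initial(hap: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> None:
    """Redraw any initial aa genotype cell until no individual is aa."""
    while True:
        aa = hap.sum(axis=1) == 2  # (n, L)
        if not aa.any():
            return
        ind, loc = np.nonzero(aa)
        hap[ind, rng.integers(0, 2, size=len(ind)), loc] = 0


def _pin_frequencies(hap: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> None:
    """Edit haplotypes in place so each locus hits round(q * 2n) copies of a.

    Additions only go on haplotypes whose partner haplotype carries A at that
    locus, so no aa individual is ever created.
    """
    n_pop = hap.shape[0]
    two_n = 2 * n_pop
    for l in range(hap.shape[2]):
        target = int(round(q[l] * two_n))
        target = max(target, 1) if q[l] > 0 else 0
        col = hap[:, :, l]
        count = int(col.sum())
        if count > target:
            ind, h = np.nonzero(col)
            drop = rng.choice(len(ind), size=count - target, replace=False)
            col[ind[drop], h[drop]] = 0
        elif count < target:
            safe = (col == 0) & (col[:, ::-1] == 0)  # partner haplotype also A
            ind, h = np.nonzero(safe)
            need = target - count
            if need > len(ind):
                raise RuntimeError("not enough safe slots to raise allele frequency")
            # at most one addition per individual, to keep additions aa-safe
            order = rng.permutation(len(ind))
            used: set[int] = set()
            added = 0
            for k in order:
                if added == need:
                    break
                if int(ind[k]) in used:
                    continue
                col[ind[k], h[k]] = 1
                used.add(int(ind[k]))
                added += 1
            if added < need:
                raise RuntimeError("not enough carrier-free individuals to pin frequency")


def sample_offspring_locus(
    g_sire: int,
    g_dam: int,
    n: int,
    rng: np.random.Generator,
    reject_lethal: bool = True,
) -> np.ndarray:
    """Vectorized single-locus Mendelian offspring sampler.

    Each parent transmits allele a with probability g/2.  With
    ``reject_lethal``, aa draws are redrawn (the conditional ratio from an
    Aa x Aa mating is then 2/3 Aa : 1/3 AA).
    """
    ps, pd_ = g_sire / 2.0, g_dam / 2.0
    out = (rng.random(n) < ps).astype(np.int8) + (rng.random(n) < pd_).astype(np.int8)
    if reject_lethal:
        if ps == 1.0 and pd_ == 1.0:
            raise RuntimeError("aa x aa mating cannot produce a surviving offspring")
        while True:
            dead = out == 2
            k = int(dead.sum())
            if k == 0:
                break
            out[dead] = (rng.random(k) < ps).astype(np.int8) + (
                rng.random(k) < pd_
            ).astype(np.int8)
    return out


def drop_genotypes(
    ped: Pedigree,
    pool: FounderPool,
    seed: int,
    linked: bool = False,
    gmap: GenomeMap | None = None,
    max_retries: int = 10_000,
) -> GenotypeState:
    """Drop founder alleles through the pedigree by Mendelian segregation.

    Founders (animals with both parents unknown) draw a diploid individual
    from the founder pool; an unknown single parent contributes a random pool
    gamete.  Each non-founder receives one gamete per parent; by default loci
    segregate independently (the panel's loci are sparse on 29 chromosomes, so
    linkage is immaterial to single-locus lethality accounting), while
    ``linked=True`` recombines gametes along the genome map.  Offspring drawn
    aa at any locus are redrawn — the recorded pedigree holds survivors only.
    """
    if linked and gmap is None:
        raise ValueError("linked mode requires a genome map")
    rng = np.random.default_rng(seed)
    hap_pool = pool.haplotypes
    n_pool, _, L = hap_pool.shape
    par = ped.parent_indices()
    n = len(ped)
    hap = np.zeros((n, 2, L), dtype=np.int8)
    r_adj = gmap.adjacent_recombination() if (linked and L > 1) else None

    def parent_gamete(idx: int) -> np.ndarray:
        if idx < 0:  # unknown parent: random gamete from the base population
            donor = int(rng.integers(n_pool))
            src = hap_pool[donor]
        else:
            src = hap[idx]
        if not linked or L == 1:
            pick = rng.integers(0, 2, size=L)
        else:
            start = int(rng.integers(2))
            switches = rng.random(L - 1) < r_adj
            pick = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
        return src[pick, np.arange(L)]

    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            hap[i] = hap_pool[int(rng.integers(n_pool))]
            continue
        for _ in range(max_retries):
            g0, g1 = parent_gamete(s), parent_gamete(d)
            if not np.any((g0 == 1) & (g1 == 1)):
                hap[i, 0], hap[i, 1] = g0, g1
                break
        else:
            raise RuntimeError(
                f"could not draw a surviving genotype for animal {ped.animals[i].id!r}"
            )

    return GenotypeState(genotypes=hap.sum(axis=1).astype(np.int8), ids=ped.ids)
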