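"""Synthetic herd generator.

The study population this package targets — a commercial-scale Angus herd
with 85 male candidates, 169 female candidates and 546 pedigree ancestors —
is private, so analyses run on synthetic stand-ins with the same shape:

* a multi-generation pedigree of configurable size whose youngest cohort are
  the selection candidates;
* per-animal EPDs (expected progeny differences) for the maternal-index
  criteria traits, drawn with the covariance structure implied by published
  heritabilities and genetic correlations for Angus/British-breed populations;
* loss-of-function (LOF) locus panels matching the three study scenarios:
  A = 7 high-frequency loci, B = 76 low-frequency loci, C = 50 mixed loci.

All draws are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_pedigree

__all__ = [
    "TRAITS",
    "TraitModel",
    "LocusPanel",
    "PANEL_SPECS",
    "generate_pedigree",
    "generate_epds",
    "generate_locus_panel",
]

#: criteria/objective traits: heifer pregnancy, calving ease direct, calving
#: ease maternal, weaning weight direct, weaning weight maternal (milk),
#: back-fat thickness, stayability.
TRAITS = ("HP", "CED", "CEM", "WWD", "WWM", "FT", "STAY")

# Literature heritabilities (diagonal) and genetic correlations
# (upper triangle) for the seven traits.
_DEFAULT_H2 = {
    "HP": 0.21,
    "CED": 0.20,
    "CEM": 0.10,
    "WWD": 0.20,
    "WWM": 0.14,
    "FT": 0.40,
    "STAY": 0.15,
}
_DEFAULT_RG = {
    ("HP", "WWD"): 0.29,
    ("CED", "CEM"): -0.30,
    ("CED", "WWD"): -0.16,
    ("CEM", "STAY"): 0.25,
    ("WWD", "WWM"): -0.17,
    ("WWD", "FT"): 0.10,
    ("WWM", "STAY"): -0.15,
    ("FT", "STAY"): 0.53,
}


def _rg_matrix(entries: dict[tuple[str, str], float]) -> pd.DataFrame:
    m = pd.DataFrame(np.eye(len(TRAITS)), index=TRAITS, columns=TRAITS)
    for (a, b), r in entries.items():
        m.loc[a, b] = m.loc[b, a] = r
    return m


@dataclass
class TraitModel:
    """Genetic parameters for the index traits.

    Phenotypic SDs and economic weights are deliberately unitless (default 1):
    the source populations' scales are not published, so all dollar outputs of
    the index are on a synthetic scale.
    """

    h2: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_H2))
    rg: pd.DataFrame = field(default_factory=lambda: _rg_matrix(_DEFAULT_RG))
    phenotypic_sd: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TRAITS}
    )
    psd_repaired: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        for t, h in self.h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2[{t}] = {h} outside [0, 1]")
        rg = self.rg.loc[list(self.h2), list(self.h2)]
        if not np.allclose(rg.to_numpy(), rg.to_numpy().T):
            raise ValueError("genetic correlation matrix must be symmetric")
        if np.any(np.abs(rg.to_numpy()) > 1 + 1e-12):
            raise ValueError("genetic correlations must lie in [-1, 1]")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.h2)

    def genetic_covariance(self) -> pd.DataFrame:
        """Genetic (co)variance matrix G from h2, r_g and phenotypic SDs.

        sigma_g,i = sqrt(h2_i) * SD_i and G_ij = r_g,ij * sigma_g,i * sigma_g,j.
        If the assembled matrix is indefinite it is projected to the nearest
        positive semidefinite matrix (eigenvalue clipping); the repair is
        recorded on ``psd_repaired`` and warned once.
        """
        traits = list(self.traits)
        sg = np.array([np.sqrt(self.h2[t]) * self.phenotypic_sd[t] for t in traits])
        G = self.rg.loc[traits, traits].to_numpy() * np.outer(sg, sg)
        w, V = np.linalg.eigh(G)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            G = (V * np.clip(w, 0.0, None)) @ V.T
            G = (G + G.T) / 2.0
            self.psd_repaired = True
            warnings.warn("genetic covariance was not PSD; clipped to nearest PSD")
        return pd.DataFrame(G, index=traits, columns=traits)


@dataclass(frozen=True)
class LocusPanel:
    """Minor (LOF) allele frequencies for one scenario."""

    frequencies: np.ndarray
    scenario: str

    def __post_init__(self) -> None:
        q = np.asarray(self.frequencies, dtype=float)
        if np.any(q <= 0.0) or np.any(q >= 1.0):
            raise ValueError("LOF frequencies must lie in (0, 1)")
        object.__setattr__(self, "frequencies", q)

    def __len__(self) -> int:
        return len(self.frequencies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus": [f"L{i:03d}" for i in range(len(self))], "freq": self.frequencies}
        )


#: study scenario panels: (n_loci, mean, sd, min, max) of LOF frequencies.
PANEL_SPECS = {
    "A": dict(n=7, mean=0.0847, sd=0.0151, fmin=0.0527, fmax=0.1001),
    "B": dict(n=76, mean=0.0112, sd=0.0125, fmin=0.0004, fmax=0.0695),
    "C": dict(n=50, mean=0.0488, sd=0.0307, fmin=0.0044, fmax=0.1436),
}


def generate_locus_panel(scenario: str, seed: int) -> LocusPanel:
    """Draw a LOF frequency panel matching a scenario's summary statistics.

    The panel contains the scenario's stated minimum and maximum exactly; the
    interior frequencies are beta-distributed on [min, max] and then shifted
    (clipped to the bounds) until the panel mean is within 5e-3 of the target.
    """
    if scenario not in PANEL_SPECS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of A, B, C")
    spec = PANEL_SPECS[scenario]
    n, mean = spec["n"], spec["mean"]
    fmin, fmax = spec["fmin"], spec["fmax"]
    rng = np.random.default_rng(seed)

    interior_mean = (n * mean - fmin - fmax) / (n - 2)
    p = (interior_mean - fmin) / (fmax - fmin)
    var_frac = (spec["sd"] / (fmax - fmin)) ** 2
    k = max(p * (1 - p) / var_frac - 1.0, 0.5)
    x = fmin + (fmax - fmin) * rng.beta(p * k, (1 - p) * k, size=n - 2)
    # nudge the interior toward the exact target mean, respecting the bounds
    for _ in range(200):
        delta = interior_mean - x.mean()
        if abs(delta) < 1e-6:
            break
        x = np.clip(x + delta, fmin, fmax)
    q = np.sort(np.concatenate([[fmin, fmax], x]))
    return LocusPanel(frequencies=q, scenario=scenario)


def generate_pedigree(
    n_ancestors: int,
    n_male_cand: int,
    n_female_cand: int,
    n_generations: int = 4,
    seed: int = 0,
    max_sire_offspring: int = 25,
    max_dam_offspring: int = 8,
) -> Pedigree:
    """Simulate a herd pedigree whose youngest cohort is the candidate cohort.

    Ancestors are split over ``n_generations`` cohorts; the first cohort are
    founders (unknown parents) and later animals draw a sire and dam at random
    from earlier cohorts, subject to per-parent offspring caps.  Candidates
    (85 M + 169 F at study scale) form one final cohort with both parents
    among the ancestors.
    """
    if min(n_ancestors, n_male_cand, n_female_cand) <= 0:
        raise ValueError("all counts must be positive")
    if n_generations < 2:
        raise ValueError("need at least 2 generations")
    rng = np.random.default_rng(seed)

    # cohort sizes for ancestors, front-loaded so founders are plentiful
    base = n_ancestors // n_generations
    sizes = [base] * n_generations
    sizes[0] += n_ancestors - base * n_generations
    # borrow from later cohorts so the founder cohort holds both sexes
    for g in range(n_generations - 1, 0, -1):
        while sizes[0] < 2 and sizes[g] > 0:
            sizes[g] -= 1
            sizes[0] += 1
    if sizes[0] < 2:
        raise ValueError("need at least two ancestors to supply both sexes")

    rows: list[dict[str, object]] = []
    males: list[str] = []
    females: list[str] = []
    capacity: dict[str, int] = {}
    next_id = 1

    def add_animal(sire: str, dam: str, sex: str, role: str) -> None:
        nonlocal next_id
        rows.append(
            {"id": str(next_id), "sire": sire, "dam": dam, "sex": sex, "role": role}
        )
        aid = str(next_id)
        next_id += 1
        if sex == "M":
            males.append(aid)
            capacity[aid] = max_sire_offspring
        else:
            females.append(aid)
            capacity[aid] = max_dam_offspring

    def pick_parent(pool: list[str]) -> str:
        avail = [p for p in pool if capacity[p] > 0]
        if not avail:
            raise ValueError(
                "infeasible pedigree shape: parent capacity exhausted "
                "(too many offspring per generation)"
            )
        choice = avail[int(rng.integers(len(avail)))]
        capacity[choice] -= 1
        return choice

    def cohort_sexes(size: int) -> list[str]:
        sexes = ["M" if rng.random() < 0.5 else "F" for _ in range(size)]
        if size >= 2:  # every cohort keeps both sexes represented
            if "M" not in sexes:
                sexes[0] = "M"
            if "F" not in sexes:
                sexes[-1] = "F"
        return sexes

    for g, size in enumerate(sizes):
        sexes = cohort_sexes(size)
        if g == 0:
            for sex in sexes:
                add_animal("0", "0", sex, "ancestor")
        else:
            # freeze the parent pools before the cohort starts so that
            # within-cohort matings cannot occur
            sire_pool, dam_pool = list(males), list(females)
            for sex in sexes:
                add_animal(pick_parent(sire_pool), pick_parent(dam_pool), sex, "ancestor")

    sire_pool, dam_pool = list(males), list(females)
    n_cand = n_male_cand + n_female_cand
    if n_cand > sum(capacity[p] for p in dam_pool):
        raise ValueError("infeasible: not enough dam capacity for candidate cohort")
    cand_sexes = ["M"] * n_male_cand + ["F"] * n_female_cand
    rng.shuffle(cand_sexes)
    for sex in cand_sexes:
        add_animal(pick_parent(sire_pool), pick_parent(dam_pool), sex, "candidate")

    return build_pedigree(rows)


def generate_epds(
    ped: Pedigree,
    model: TraitModel,
    seed: int,
    missing_fraction: float = 0.0,
    trait_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-animal EPD vectors for the model's traits.

    EPDs are sampled i.i.d. multivariate normal around the trait means with
    covariance = 1/4 x genetic covariance (an EPD transmits half the breeding
    value, and parent-average information is taken as the accuracy proxy).  A
    ``missing_fraction`` of animals receive the breed-average (mean) vector,
    emulating animals without reported EPDs.

    Returns a DataFrame indexed by animal id with one column per trait.
    """
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError("missing_fraction must lie in [0, 1]")
    traits = list(model.traits)
    mu = np.array([(trait_means or {}).get(t, 0.0) for t in traits])
    cov = 0.25 * model.genetic_covariance().to_numpy()
    rng = np.random.default_rng(seed)
    n = len(ped)
    values = rng.multivariate_normal(mu, cov, size=n, method="svd")
    if missing_fraction > 0:
        n_missing = int(round(missing_fraction * n))
        missing = rng.choice(n, size=n_missing, replace=False)
        values[missing] = mu
    return pd.DataFrame(values, index=pd.Index(ped.ids, name="id"), columns=traits)
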