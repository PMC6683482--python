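"""Maternal economic selection index ($M) from EPDs.

Classic selection-index theory: the index weights b on the criteria-trait
EPDs solve G_cc b = G_co v, where G_cc is the genetic covariance among the
criteria traits, G_co the genetic covariance between criteria and breeding
objective traits, and v the economic weights on the objective.  The maternal
objective here covers heifer pregnancy, calving ease (direct and maternal),
weaning weight (direct and maternal) and stayability; the criteria replace
stayability with back-fat thickness (its genetically correlated indicator).

The genetic load score trait carries zero heritability and zero correlations,
so it contributes nothing to b and is handled entirely by the lethality
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import TraitModel

__all__ = [
    "IndexSpec",
    "index_coefficients",
    "animal_index",
    "progeny_index",
    "mating_weighted_sire_index",
]

DEFAULT_OBJECTIVE = ("HP", "CED", "CEM", "WWD", "WWM", "STAY")
DEFAULT_CRITERIA = ("HP", "CED", "CEM", "WWD", "WWM", "FT")


@dataclass
class IndexSpec:
    """Trait lists and economic weights defining the maternal index.

    Economic weights default to 1 per objective trait: the study's literature
    weights are unpublished, so index dollars are on a synthetic unit scale.
    """

    objective: tuple[str, ...] = DEFAULT_OBJECTIVE
    criteria: tuple[str, ...] = DEFAULT_CRITERIA
    weights: dict[str, float] = field(default_factory=dict)

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(t, 1.0) for t in self.objective])


def index_coefficients(model: TraitModel, spec: IndexSpec) -> pd.Series:
    """Solve G_cc b = G_co v for the index coefficients b (one per criterion)."""
    G = model.genetic_covariance()
    missing = [t for t in set(spec.criteria) | set(spec.objective) if t not in G.index]
    if missing:
        raise ValueError(f"traits not in the trait model: {missing}")
    G_cc = G.loc[list(spec.criteria), list(spec.criteria)].to_numpy()
    G_co = G.loc[list(spec.criteria), list(spec.objective)].to_numpy()
    rhs = G_co @ spec.weight_vector()
    try:
        b = np.linalg.solve(G_cc, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("criteria covariance matrix is singular") from exc
    return pd.Series(b, index=list(spec.criteria), name="b")


def animal_index(epds: pd.DataFrame | pd.Series, b: pd.Series) -> pd.Series | float:
    """$M = b . EPD for one animal (Series) or a table of animals (DataFrame)."""
    missing = [t for t in b.index if t not in getattr(epds, "columns", epds.index)]
    if missing:
        raise ValueError(f"EPD vector missing criteria traits: {missing}")
    if isinstance(epds, pd.Series):
        return float(epds[b.index] @ b)
    out = epds[b.index] @ b
    out.name = "M"
    return out


def progeny_index(sire_m: float, dam_m: float) -> float:
    """Mid-parent progeny index: additive EPDs make this the expected progeny $M."""
    return 0.5 * (sire_m + dam_m)


def mating_weighted_sire_index(
    matings: list[tuple[str, str]], m_values: pd.Series
) -> float:
    """$MB: average sire index over the mating list, weighted by use.

    $MB = sum_s n_s $M_s / sum_s n_s over the sires s appearing in the list.
    """
    if len(matings) == 0:
        raise ValueError("empty mating list")
    sires = [s for s, _ in matings]
    return float(np.mean([m_values[s] for s in sires]))
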