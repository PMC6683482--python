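"""Study driver: scenarios x strategies x weightings x genotyping tiers.

A study cell is one optimized mating run: a scenario fixes the lethal-locus
panel (A = 7 high-frequency, B = 76 low-frequency, C = 50 mixed), a strategy
fixes which lethality penalty carries the weighting (1 = LethalA, carrier
avoidance; 2 = LethalG, carrier-mating avoidance), a tier fixes the
percentage of the candidate herd whose true genotypes are revealed, and each
replicate re-drops true genotypes through the fixed pedigree.

The decisions/outcomes split: the optimizer only ever sees the genotype
probabilities inferred by segregation analysis from the genotyped subset;
realized mortality, GLS and profit are then scored against the true
genotypes.  This is the only reading under which partial genotyping can
change outcomes.

Seed discipline: every random stage draws from a named substream of the
master seed (``pedigree``, ``epd``, ``panel``, ``drop:<rep>``,
``scheme:<rep>``, ``ea:<cell>``), so any cell can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import econ as _econ
from ._rng import substream_seed
from .genedrop import GenomeMap, burn_in_founders, drop_genotypes
from .index import IndexSpec, animal_index, index_coefficients, mating_weighted_sire_index
from .lethal import genetic_load_score, lethal_a, lethal_g
from .matesel import MateSelContext, ObjectiveConfig, solve_at_degrees
from .pedigree import kinship_matrix
from .segprob import SegregationAnalyzer, assign_genotyping, genotype_probabilities_all_loci
from .synth import TraitModel, generate_epds, generate_locus_panel, generate_pedigree

__all__ = ["StudyConfig", "StudyContext", "prepare_study", "run_cell", "sweep",
           "summarize", "profit_max_weighting"]

DEFAULT_GRID = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_TIERS = tuple(range(0, 101, 10))


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study sweep."""

    scenario: str = "C"
    strategy: int = 2
    weighting_grid: tuple[float, ...] = DEFAULT_GRID
    tiers: tuple[int, ...] = DEFAULT_TIERS
    n_replicates: int = 100
    master_seed: int = 1
    # herd shape (study scale by default)
    n_ancestors: int = 546
    n_male_candidates: int = 85
    n_female_candidates: int = 169
    n_pedigree_generations: int = 4
    # founder burn-in
    burn_in_population: int = 500
    burn_in_generations: int = 1000
    missing_epd_fraction: float = 0.0
    empirical_frequencies: bool = True  # LethalA's q from candidate posteriors
    econ: _econ.EconConfig = field(default_factory=_econ.EconConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)

    def __post_init__(self) -> None:
        if self.strategy not in (1, 2):
            raise ValueError("strategy must be 1 (LethalA) or 2 (LethalG)")


@dataclass
class StudyContext:
    """Per-scenario artifacts shared by all replicates (pedigree/EPDs fixed)."""

    cfg: StudyConfig
    ped: object
    panel: object
    pool: object
    m_values: pd.Series
    kinship: pd.DataFrame
    analyzer: SegregationAnalyzer


def prepare_study(cfg: StudyConfig) -> StudyContext:
    """Generate the fixed artifacts: pedigree, EPDs, index values, kinship, panel."""
    seed = cfg.master_seed
    ped = generate_pedigree(
        cfg.n_ancestors,
        cfg.n_male_candidates,
        cfg.n_female_candidates,
        cfg.n_pedigree_generations,
        seed=substream_seed(seed, "pedigree"),
    )
    model = TraitModel()
    epds = generate_epds(
        ped, model, seed=substream_seed(seed, "epd"),
        missing_fraction=cfg.missing_epd_fraction,
    )
    b = index_coefficients(model, IndexSpec())
    m_values = animal_index(epds, b)
    kin = kinship_matrix(ped)
    panel = generate_locus_panel(cfg.scenario, seed=substream_seed(seed, "panel", cfg.scenario))
    gmap = GenomeMap.random(len(panel), seed=substream_seed(seed, "map", cfg.scenario))
    pool = burn_in_founders(
        panel, gmap,
        n_pop=cfg.burn_in_population,
        n_generations=cfg.burn_in_generations,
        seed=substream_seed(seed, "burnin", cfg.scenario),
    )
    analyzer = SegregationAnalyzer(ped)
    return StudyContext(cfg=cfg, ped=ped, panel=panel, pool=pool,
                        m_values=m_values, kinship=kin, analyzer=analyzer)


def _point_probs(genotypes_row: np.ndarray) -> np.ndarray:
    out = np.zeros((len(genotypes_row), 3))
    out[np.arange(len(genotypes_row)), genotypes_row] = 1.0
    return out


def _cell_objective(cfg: StudyConfig, weighting: float, seed: int) -> ObjectiveConfig:
    o = replace(cfg.objective, seed=seed)
    if cfg.strategy == 1:
        return replace(o, w_a=weighting, w_g=0.0)
    return replace(o, w_a=0.0, w_g=weighting)


def run_cell(
    cfg: StudyConfig,
    weighting: float,
    tier: int,
    replicate: int,
    study: StudyContext | None = None,
    _rep_cache: dict | None = None,
) -> dict:
    """One optimized mating run, scored on true genotypes.

    Returns a flat record with the decision-side metrics (what the optimizer
    believed) and the realized outcomes (mortality, GLS, $P on truth).
    """
    study = study or prepare_study(cfg)
    ped, panel = study.ped, study.panel
    seed = cfg.master_seed
    cache = _rep_cache if _rep_cache is not None else {}

    cand_ids = [a.id for a in ped.candidates()]
    if "genotypes" not in cache:
        cache["genotypes"] = drop_genotypes(
            ped, study.pool, seed=substream_seed(seed, "drop", cfg.scenario, replicate)
        )
        cache["scheme"] = assign_genotyping(
            cand_ids, sorted(set(cfg.tiers) | {tier}),
            seed=substream_seed(seed, "scheme", cfg.scenario, replicate),
        )
    state = cache["genotypes"]
    scheme = cache["scheme"]

    probs_key = ("probs", tier)
    if probs_key not in cache:
        genotyped = scheme.genotyped_at(tier)
        post = genotype_probabilities_all_loci(
            ped, state.genotypes, genotyped, panel.frequencies, analyzer=study.analyzer
        )
        cache[probs_key] = {a: post[ped.index_of(a)] for a in cand_ids}
    probs = cache[probs_key]

    if cfg.empirical_frequencies:
        q_eff = np.mean(
            [0.5 * probs[a][:, 1] + probs[a][:, 2] for a in cand_ids], axis=0
        )
        q_eff = np.clip(q_eff, 1e-9, 1.0)
    else:
        q_eff = panel.frequencies

    ocfg = _cell_objective(
        cfg, weighting,
        substream_seed(seed, "ea", cfg.scenario, cfg.strategy, weighting, tier, replicate),
    )
    ctx = MateSelContext.from_pedigree(ped, study.m_values, study.kinship, probs, q_eff)
    matings, frontier, ev = solve_at_degrees(ctx, ocfg)

    # realized outcomes on truth
    truth = {a: _point_probs(state.of(a)) for a in cand_ids}
    q_true = np.clip(
        np.mean([state.of(a) for a in cand_ids], axis=0) / 2.0, 1e-9, 1.0
    )
    lg_true = lethal_g(matings, truth)
    la_true = lethal_a(matings, truth, q_true,
                       survivor_condition=ocfg.survivor_condition)
    gls_true = genetic_load_score(matings, truth, panel.frequencies)
    mean_m = float(np.mean([
        0.5 * (study.m_values[s] + study.m_values[d]) for s, d in matings
    ]))
    mb = mating_weighted_sire_index(matings, study.m_values)
    p_dollars = _econ.profit_per_mating(mean_m, lg_true, cfg.econ, rounded=False)

    return {
        "scenario": cfg.scenario,
        "strategy": cfg.strategy,
        "weighting": weighting,
        "pct_genotyped": tier,
        "replicate": replicate,
        "meanM": mean_m,
        "MB": mb,
        "lethalA": la_true,
        "lethalG": lg_true,
        "gls": gls_true,
        "P": p_dollars,
        "affected_per_100": 100.0 * lg_true,
        "believed_lethalG": ev.lethal_g,
        "coancestry": ev.coancestry,
        "angle_degrees": frontier.angle_degrees,
        "converged": frontier.converged,
    }


def sweep(cfg: StudyConfig, study: StudyContext | None = None) -> pd.DataFrame:
    """Full factorial over weighting grid x tiers x replicates (long format).

    Per replicate, the true genotypes and the nested genotyping scheme are
    drawn once and shared across weightings and tiers; tier-0 outcomes anchor
    the savings/net-profit/breakeven columns of every other tier in the same
    (weighting, replicate) slice.
    """
    study = study or prepare_study(cfg)
    rows = []
    for rep in range(cfg.n_replicates):
        cache: dict = {}
        for tier in cfg.tiers:
            for w in cfg.weighting_grid:
                rows.append(run_cell(cfg, w, tier, rep, study=study, _rep_cache=cache))
    df = pd.DataFrame(rows)

    # economics relative to each slice's own 0%-genotyped base run
    base = (
        df[df["pct_genotyped"] == 0]
        .set_index(["weighting", "replicate"])["affected_per_100"]
        .rename("base_affected")
    )
    if len(base):
        df = df.join(base, on=["weighting", "replicate"])
        df["savings"] = [
            _econ.savings(b, a, cfg.econ) if np.isfinite(b) else np.nan
            for b, a in zip(df["base_affected"], df["affected_per_100"])
        ]
        df["net_profit"] = [
            _econ.net_profit(s, p, cfg.econ) if np.isfinite(s) else np.nan
            for s, p in zip(df["savings"], df["pct_genotyped"])
        ]
        df["breakeven"] = [
            _econ.breakeven(s, p, cfg.econ) if (np.isfinite(s) and p > 0) else np.nan
            for s, p in zip(df["savings"], df["pct_genotyped"])
        ]
    return df


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means and standard errors over replicates."""
    keys = ["scenario", "strategy", "weighting", "pct_genotyped"]
    g = results.groupby(keys)
    out = g.agg(
        mean_P=("P", "mean"),
        se_P=("P", "sem"),
        mean_affected=("affected_per_100", "mean"),
        se_affected=("affected_per_100", "sem"),
        mean_MB=("MB", "mean"),
        mean_gls=("gls", "mean"),
        n=("P", "size"),
    ).reset_index()
    return out.fillna({"se_P": 0.0, "se_affected": 0.0})


def profit_max_weighting(summary: pd.DataFrame) -> pd.DataFrame:
    """Weighting maximizing mean $P per scenario/strategy/tier (ties -> smaller)."""
    keys = ["scenario", "strategy", "pct_genotyped"]
    rows = []
    for k, grp in summary.groupby(keys):
        grp = grp.sort_values("weighting", kind="stable")
        best = grp.loc[grp["mean_P"].idxmax()]
        rows.append(dict(zip(keys, k)) | {
            "weighting": best["weighting"], "mean_P": best["mean_P"],
        })
    return pd.DataFrame(rows)
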