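"""Segregation analysis: genotype probabilities for partly genotyped herds.

Given a pedigree, observed genotypes at a biallelic lethal locus for a subset
of animals, and a base-population allele frequency q, this module computes
each animal's posterior genotype distribution (P_AA, P_Aa, P_aa) conditional
on *all* observed genotypes.  Founders carry a Hardy-Weinberg prior at q;
Mendelian transmission links parents and offspring.

Inference is exact whenever the pedigree's moralized graph admits a
low-width elimination order (this includes every loop-free pedigree and the
inbreeding/mate-sharing loops typical of herd pedigrees): a bucket
(junction) tree is built once per pedigree and calibrated with an upward and
a downward pass, yielding all marginals in two sweeps.  If the induced width
is too large for exact elimination, iterative peeling (damped sum-product on
the factor graph) is used instead; it is exact on loop-free pedigrees and
approximate on loops.

Posteriors are not conditioned on ungenotyped animals being alive (hence not
aa); pass ``condition_alive=True`` to add that constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GenotypingScheme",
    "MendelianInconsistencyError",
    "SegregationAnalyzer",
    "assign_genotyping",
    "genotype_probabilities",
    "genotype_probabilities_all_loci",
]


class MendelianInconsistencyError(ValueError):
    """Observed genotypes are impossible under Mendelian inheritance."""


class _WidthExceeded(Exception):
    pass


# ---------------------------------------------------------------------------
# genotyping schemes


@dataclass
class GenotypingScheme:
    """Nested random genotyping subsets across percentage tiers.

    An animal genotyped at tier t stays genotyped at every higher tier, so
    increasing the budget only adds information.
    """

    tiers: list[int]
    subsets: dict[int, list[str]]

    def genotyped_at(self, tier: int) -> list[str]:
        if tier not in self.subsets:
            raise KeyError(f"tier {tier} not in scheme (tiers: {self.tiers})")
        return self.subsets[tier]


def assign_genotyping(
    herd: "Pedigree | list[str]", tiers: list[int], seed: int
) -> GenotypingScheme:
    """Draw one herd permutation and cut it at round(pct% x herd size) per tier.

    ``herd`` is a pedigree (all its animals are eligible) or an explicit id
    list (e.g. the candidate cohort).
    """
    if any(not 0 <= t <= 100 for t in tiers):
        raise ValueError("tiers must lie in [0, 100]")
    if sorted(tiers) != list(tiers):
        raise ValueError("tiers must be sorted ascending")
    rng = np.random.default_rng(seed)
    ids = list(herd.ids) if isinstance(herd, Pedigree) else list(herd)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    subsets = {t: sorted(perm[: int(round(t / 100.0 * len(ids)))]) for t in tiers}
    return GenotypingScheme(tiers=list(tiers), subsets=subsets)


# ---------------------------------------------------------------------------
# factor utilities (genotype domain: 0 = AA, 1 = Aa, 2 = aa)


def _transmission(q: float | None) -> np.ndarray:
    """P(transmit a | parent genotype); an unknown parent transmits a w.p. q."""
    if q is None:
        return np.array([0.0, 0.5, 1.0])
    return np.array([q, q, q])


def _hwe_prior(q: float) -> np.ndarray:
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def _child_table(ts: np.ndarray, td: np.ndarray) -> np.ndarray:
    """P(child | sire, dam) from per-genotype a-transmission probabilities.

    Shapes broadcast: returns (3 child, len(ts), len(td)).
    """
    s = ts[:, None]
    d = td[None, :]
    return np.stack([(1 - s) * (1 - d), s * (1 - d) + d * (1 - s), s * d])


_T = np.array([0.0, 0.5, 1.0])  # a-transmission by parent genotype


@dataclass
class _Factor:
    vars: tuple[int, ...]
    table: np.ndarray


def _product(factors: list[_Factor]) -> _Factor:
    scope = sorted(set().union(*[f.vars for f in factors]))
    pos = {v: i for i, v in enumerate(scope)}
    out = np.ones((3,) * len(scope))
    for f in factors:
        axes = [pos[v] for v in f.vars]
        expanded = np.moveaxis(
            f.table.reshape(f.table.shape + (1,) * (len(scope) - len(f.vars))),
            range(len(f.vars)),
            axes,
        )
        out = out * expanded
    return _Factor(tuple(scope), out)


def _sum_out(f: _Factor, var: int) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(tuple(v for v in f.vars if v != var), f.table.sum(axis=axis))


# ---------------------------------------------------------------------------
# the analyzer


class SegregationAnalyzer:
    """Per-pedigree inference engine for single-locus genotype posteriors.

    The factor-graph structure (and, for exact mode, the elimination order
    and bucket tree) depends only on the pedigree, so one analyzer serves any
    number of loci, allele frequencies and genotyping patterns.
    """

    def __init__(
        self,
        ped: Pedigree,
        condition_alive: bool = False,
        max_width: int = 12,
        damping: float = 0.5,
        tol: float = 1e-8,
        max_iter: int = 2000,
    ):
        self.ped = ped
        self.condition_alive = condition_alive
        self.max_width = max_width
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter
        self.n = len(ped)
        self._par = ped.parent_indices()
        # scopes of the structural factors: one per animal
        self._scopes: list[tuple[int, ...]] = []
        for i in range(self.n):
            s, d = self._par[i]
            scope = (i,) + tuple(p for p in (s, d) if p >= 0)
            self._scopes.append(scope)
        self._order: list[int] | None = None
        self._order_ok: bool | None = None

    # -- structural factor tables, which depend on q only ------------------

    def _factor_tables(self, q: float) -> list[_Factor]:
        factors = []
        prior = _hwe_prior(q)
        for i in range(self.n):
            s, d = self._par[i]
            if s < 0 and d < 0:
                factors.append(_Factor((i,), prior.copy()))
            elif s >= 0 and d >= 0:
                factors.append(_Factor((i, s, d), _child_table(_T, _T)))
            else:
                known = s if s >= 0 else d
                # unknown parent integrated against its HWE prior
                tbl = np.einsum("csd,d->cs", _child_table(_T, _T), prior)
                factors.append(_Factor((i, known), tbl))
        return factors

    # -- evidence ----------------------------------------------------------

    def _evidence_factors(self, observed: dict[int, int]) -> list[_Factor]:
        out = []
        for i, g in observed.items():
            e = np.zeros(3)
            e[g] = 1.0
            out.append(_Factor((i,), e))
        if self.condition_alive:
            alive = np.array([1.0, 1.0, 0.0])
            for i in range(self.n):
                if i not in observed:
                    out.append(_Factor((i,), alive.copy()))
        return out

    def _check_trios(self, observed: dict[int, int]) -> None:
        """Catch direct trio inconsistencies with a named error."""
        for i in range(self.n):
            s, d = self._par[i]
            if i not in observed:
                continue
            gc = observed[i]
            ts = _T[[observed[s]]] if (s >= 0 and s in observed) else _T
            td = _T[[observed[d]]] if (d >= 0 and d in observed) else _T
            if _child_table(ts, td)[gc].max() <= 0.0:
                ids = self.ped.ids
                raise MendelianInconsistencyError(
                    f"genotypes of trio (child={ids[i]}, sire={ids[s] if s >= 0 else '?'}"
                    f", dam={ids[d] if d >= 0 else '?'}) violate Mendelian inheritance"
                )

    # -- elimination order (min-fill on the moral graph) -------------------

    def _elimination_order(self) -> list[int]:
        if self._order is not None:
            return self._order
        adj: list[set[int]] = [set() for _ in range(self.n)]
        for scope in self._scopes:
            for a in scope:
                for b in scope:
                    if a != b:
                        adj[a].add(b)
        remaining = set(range(self.n))
        order: list[int] = []
        while remaining:
            best, best_fill = None, None
            for v in remaining:
                nb = adj[v] & remaining
                fill = sum(
                    1
                    for a in nb
                    for b in nb
                    if a < b and b not in adj[a]
                )
                if best_fill is None or fill < best_fill or (
                    fill == best_fill and v < best
                ):
                    best, best_fill = v, fill
            nb = adj[best] & remaining
            for a in nb:
                for b in nb:
                    if a != b:
                        adj[a].add(b)
            order.append(best)
            remaining.discard(best)
        self._order = order
        return order

    # -- exact inference: bucket-tree calibration --------------------------

    def _exact_marginals(self, factors: list[_Factor]) -> np.ndarray:
        order = self._elimination_order()
        pos = {v: k for k, v in enumerate(order)}
        buckets: list[list[_Factor]] = [[] for _ in range(self.n)]
        for f in factors:
            buckets[min(f.vars, key=pos.__getitem__)].append(f)

        up_msg: list[_Factor | None] = [None] * self.n  # message sent by bucket v
        parent: list[int | None] = [None] * self.n
        children: list[list[int]] = [[] for _ in range(self.n)]
        bucket_inputs: list[list[_Factor]] = [list(b) for b in buckets]

        for v in order:
            psi = _product(bucket_inputs[v])
            if len(psi.vars) - 1 > self.max_width:
                raise _WidthExceeded
            lam = _sum_out(psi, v)
            z = lam.table.sum() if lam.vars else float(lam.table)
            if z <= 0.0:
                raise MendelianInconsistencyError(
                    "observed genotypes are jointly impossible under Mendelian "
                    f"inheritance (detected eliminating animal {self.ped.ids[v]!r})"
                )
            lam = _Factor(lam.vars, lam.table / z)
            up_msg[v] = lam
            if lam.vars:
                p = min(lam.vars, key=pos.__getitem__)
                parent[v] = p
                children[p].append(v)
                bucket_inputs[p].append(lam)

        down_msg: list[_Factor | None] = [None] * self.n  # from parent into bucket v
        marginals = np.zeros((self.n, 3))
        for v in reversed(order):
            own = list(buckets[v])
            child_msgs = {c: up_msg[c] for c in children[v]}
            incoming = [down_msg[v]] if down_msg[v] is not None else []
            belief = _product(own + list(child_msgs.values()) + incoming)
            # marginal of v
            m = belief
            for w in m.vars:
                if w != v:
                    m = _sum_out(m, w)
            total = m.table.sum()
            if total <= 0.0:
                raise MendelianInconsistencyError(
                    f"zero posterior mass at animal {self.ped.ids[v]!r}"
                )
            marginals[v] = m.table / total
            # downward messages to each child bucket
            for c in children[v]:
                parts = own + [msg for cc, msg in child_msgs.items() if cc != c]
                if down_msg[v] is not None:
                    parts.append(down_msg[v])
                sep = set(up_msg[c].vars)
                if parts:
                    f = _product(parts)
                else:
                    f = _Factor((), np.array(1.0))
                for w in f.vars:
                    if w not in sep:
                        f = _sum_out(f, w)
                z = f.table.sum() if f.vars else 1.0
                down_msg[c] = _Factor(f.vars, f.table / z if z > 0 else f.table)
        return marginals

    # -- iterative peeling (damped sum-product) ----------------------------

    def _loopy_marginals(self, factors: list[_Factor]) -> np.ndarray:
        # split unary evidence into per-variable potentials; keep multi-var factors
        unary = np.ones((self.n, 3))
        multi: list[_Factor] = []
        for f in factors:
            if len(f.vars) == 1:
                unary[f.vars[0]] *= f.table
            else:
                multi.append(f)
        # messages: factor->var and var->factor, uniform init
        f2v = [
            {v: np.ones(3) / 3 for v in f.vars} for f in multi
        ]
        v2f: list[dict[int, np.ndarray]] = [
            {v: np.ones(3) / 3 for v in f.vars} for f in multi
        ]
        var_factors: list[list[int]] = [[] for _ in range(self.n)]
        for k, f in enumerate(multi):
            for v in f.vars:
                var_factors[v].append(k)

        for _ in range(self.max_iter):
            delta = 0.0
            # var -> factor
            for k, f in enumerate(multi):
                for v in f.vars:
                    msg = unary[v].copy()
                    for k2 in var_factors[v]:
                        if k2 != k:
                            msg = msg * f2v[k2][v]
                    z = msg.sum()
                    if z <= 0:
                        raise MendelianInconsistencyError(
                            f"zero message at animal {self.ped.ids[v]!r}"
                        )
                    v2f[k][v] = msg / z
            # factor -> var
            for k, f in enumerate(multi):
                for v in f.vars:
                    t = f.table
                    vars_ = list(f.vars)
                    for i, w in enumerate(vars_):
                        if w != v:
                            shape = [1] * len(vars_)
                            shape[i] = 3
                            t = t * v2f[k][w].reshape(shape)
                    axis = tuple(i for i, w in enumerate(vars_) if w != v)
                    msg = t.sum(axis=axis)
                    z = msg.sum()
                    if z <= 0:
                        raise MendelianInconsistencyError(
                            f"zero message into animal {self.ped.ids[v]!r}"
                        )
                    msg = msg / z
                    new = self.damping * f2v[k][v] + (1 - self.damping) * msg
                    delta = max(delta, float(np.abs(new - f2v[k][v]).max()))
                    f2v[k][v] = new
            if delta < self.tol:
                break
        marg = unary.copy()
        for k, f in enumerate(multi):
            for v in f.vars:
                marg[v] *= f2v[k][v]
        z = marg.sum(axis=1, keepdims=True)
        if np.any(z <= 0):
            bad = int(np.argmax(z[:, 0] <= 0))
            raise MendelianInconsistencyError(
                f"zero posterior mass at animal {self.ped.ids[bad]!r}"
            )
        return marg / z

    # -- public API --------------------------------------------------------

    def posteriors(self, q: float, observed: dict[str, int]) -> np.ndarray:
        """(n, 3) posterior genotype probabilities in pedigree order.

        ``observed`` maps animal id -> genotype code (0 = AA, 1 = Aa, 2 = aa).
        """
        if not 0.0 < q < 1.0:
            raise ValueError("allele frequency must lie in (0, 1)")
        obs_idx = {self.ped.index_of(a): int(g) for a, g in observed.items()}
        for g in obs_idx.values():
            if g not in (0, 1, 2):
                raise ValueError("observed genotypes must be coded 0/1/2")
        self._check_trios(obs_idx)
        factors = self._factor_tables(q) + self._evidence_factors(obs_idx)
        if self._order_ok is not False:
            try:
                out = self._exact_marginals(factors)
                self._order_ok = True
                return out
            except _WidthExceeded:
                self._order_ok = False
        return self._loopy_marginals(factors)


def genotype_probabilities(
    ped: Pedigree,
    observed: dict[str, int],
    q: float,
    condition_alive: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Posterior (pAA, pAa, paa) per animal given partial genotyping at one locus.

    Convenience wrapper around :class:`SegregationAnalyzer` returning a
    DataFrame indexed by animal id.
    """
    analyzer = SegregationAnalyzer(ped, condition_alive=condition_alive, **kwargs)
    probs = analyzer.posteriors(q, observed)
    return pd.DataFrame(
        probs, index=pd.Index(ped.ids, name="id"), columns=["pAA", "pAa", "paa"]
    )


def genotype_probabilities_all_loci(
    ped: Pedigree,
    genotypes: np.ndarray,
    genotyped_ids: list[str],
    frequencies: np.ndarray,
    condition_alive: bool = False,
    analyzer: SegregationAnalyzer | None = None,
) -> np.ndarray:
    """(n_animals, n_loci, 3) posteriors with a shared genotyped subset.

    ``genotypes`` is the (n_animals, n_loci) true-genotype array in pedigree
    order; only rows of ``genotyped_ids`` are revealed to the analyzer.  Loci
    are independent, so each is analyzed separately at its own frequency.
    """
    if analyzer is None:
        analyzer = SegregationAnalyzer(ped, condition_alive=condition_alive)
    n, L = genotypes.shape
    out = np.zeros((n, L, 3))
    gset = [(a, ped.index_of(a)) for a in genotyped_ids]
    for l in range(L):
        observed = {a: int(genotypes[i, l]) for a, i in gset}
        out[:, l, :] = analyzer.posteriors(float(frequencies[l]), observed)
    return out
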