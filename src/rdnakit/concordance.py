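"""Sharing of differentially expressed genes across contrasts and sexes.

Two routes quantify whether an observed overlap between two DE gene sets
exceeds chance: a Monte-Carlo null that repeatedly draws random subsets of
the matched sizes from the gene universe and counts their intersection, and
the closed-form hypergeometric distribution of that intersection (the exact
oracle the Monte-Carlo converges to).  A third, fully empirical route
re-runs the entire differential-expression procedure on sign-randomized
datasets and intersects the resulting calls.

The module also provides 2x2 direction-concordance tables (up/down in each
contrast, Fisher-tested) and Spearman correlations of signed or absolute
log fold-changes between contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression_model import (
    DEGeneSet,
    InsufficientDataError,
    NormalizedMatrix,
    balanced_signs,
    call_de,
    moderate_and_test,
    oriented_m,
)

__all__ = [
    "OverlapTest",
    "DirectionTable",
    "FoldChangeCorrelation",
    "mc_overlap_null",
    "hypergeometric_overlap",
    "permuted_dataset_overlap",
    "direction_table",
    "foldchange_correlation",
    "multiway_sharing",
]


@dataclass(frozen=True)
class OverlapTest:
    """Monte-Carlo null summary for the intersection of two gene sets."""

    n1: int
    n2: int
    universe_n: int
    observed_k: int
    reps: int
    null_mean: float
    null_sd: float
    null_max: int
    #: add-one empirical tail probability of an overlap >= observed_k
    empirical_p: float


@dataclass(frozen=True)
class DirectionTable:
    """2x2 direction-concordance counts over the intersection of two DE sets."""

    up_up: int
    up_down: int
    down_up: int
    down_down: int
    #: two-sided Fisher exact p; NaN (with ``undefined``) on empty intersection
    p: float
    undefined: bool

    @property
    def total(self) -> int:
        return self.up_up + self.up_down + self.down_up + self.down_down


@dataclass(frozen=True)
class FoldChangeCorrelation:
    """Spearman rank correlation of (absolute) log fold-changes."""

    rho: float
    p: float
    n_genes: int
    absolute: bool


def _check_sizes(n1: int, n2: int, universe_n: int) -> None:
    if universe_n < 1:
        raise ValueError("universe must be non-empty")
    if not (0 <= n1 <= universe_n and 0 <= n2 <= universe_n):
        raise ValueError(
            f"set sizes ({n1}, {n2}) must lie in [0, universe={universe_n}]"
        )


def mc_overlap_null(
    n1: int,
    n2: int,
    universe_n: int,
    observed_k: int,
    reps: int = 10_000,
    seed: int = 0,
) -> OverlapTest:
    """Monte-Carlo null for the overlap of two fixed-size random gene sets.

    Each replicate draws two independent uniform subsets without replacement
    of sizes ``n1`` and ``n2`` from a universe of ``universe_n`` genes and
    counts the intersection.  The empirical tail probability uses the
    add-one convention ``(1 + #{null >= observed}) / (reps + 1)`` so it can
    never be exactly zero.
    """
    _check_sizes(n1, n2, universe_n)
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if observed_k > min(n1, n2):
        raise ValueError("observed overlap exceeds the smaller set")
    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=np.int64)
    mask = np.zeros(universe_n, dtype=bool)
    for i in range(reps):
        a = rng.choice(universe_n, size=n1, replace=False)
        b = rng.choice(universe_n, size=n2, replace=False)
        mask[a] = True
        counts[i] = int(mask[b].sum())
        mask[a] = False
    empirical_p = (1 + int((counts >= observed_k).sum())) / (reps + 1)
    return OverlapTest(
        n1=n1,
        n2=n2,
        universe_n=universe_n,
        observed_k=observed_k,
        reps=reps,
        null_mean=float(counts.mean()),
        null_sd=float(counts.std(ddof=1)) if reps > 1 else 0.0,
        null_max=int(counts.max()),
        empirical_p=float(empirical_p),
    )


def hypergeometric_overlap(
    n1: int, n2: int, universe_n: int, observed_k: int
) -> tuple[float, float, float]:
    """Exact distribution of the overlap of two uniform random subsets.

    Conditioning on one subset, the intersection size follows
    ``Hypergeometric(N=universe_n, K=n1, n=n2)``.  Returns
    ``(mean, variance, P(overlap >= observed_k))``.
    """
    _check_sizes(n1, n2, universe_n)
    dist = stats.hypergeom(M=universe_n, n=n1, N=n2)
    return float(dist.mean()), float(dist.var()), float(dist.sf(observed_k - 1))


def permuted_dataset_overlap(
    matrix_a: NormalizedMatrix,
    design_a: pd.DataFrame,
    contrast_a: tuple[str, str],
    matrix_b: NormalizedMatrix,
    design_b: pd.DataFrame,
    contrast_b: tuple[str, str],
    p_cut: float = 0.005,
    fdr_cut: float | None = None,
    n_perm: int = 20,
    min_obs: int = 2,
    seed: int = 0,
) -> dict:
    """Expected shared DE count from re-analysing sign-randomized datasets.

    Per permutation each dataset's arrays get a balanced random sign flip
    (dye re-randomization cancelling genuine effects), differential
    expression is called at ``p_cut`` in each, and the intersection
    counted.  The mean of this distribution is the chance expectation for
    the number of genes called in both datasets.

    Returns a dict with ``counts`` (per-permutation shared counts),
    ``mean``, ``n_a``/``n_b`` (per-permutation DE counts in each dataset),
    and ``observed`` (the unpermuted shared count).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    oa = oriented_m(matrix_a, design_a, contrast_a)
    ob = oriented_m(matrix_b, design_b, contrast_b)

    def de_set(oriented: pd.DataFrame, label: str) -> frozenset:
        n_obs = oriented.notna().sum(axis=1)
        fits = pd.DataFrame(
            {
                "log_fc": oriented.mean(axis=1),
                "s2": oriented.var(axis=1, ddof=1),
                "df": (n_obs - 1).clip(lower=0),
                "n_obs": n_obs,
                "tested": n_obs >= min_obs,
            }
        )
        res = moderate_and_test(fits)
        return call_de(res, label, p_cut=p_cut, fdr_cut=fdr_cut).members

    observed = len(de_set(oa, "a") & de_set(ob, "b"))
    counts = np.empty(n_perm, dtype=int)
    n_a = np.empty(n_perm, dtype=int)
    n_b = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        sa = balanced_signs(rng, oa.shape[1])
        sb = balanced_signs(rng, ob.shape[1])
        set_a = de_set(oa * sa, "a")
        set_b = de_set(ob * sb, "b")
        n_a[i], n_b[i] = len(set_a), len(set_b)
        counts[i] = len(set_a & set_b)
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "n_a": n_a,
        "n_b": n_b,
        "observed": observed,
    }


def direction_table(set_a: DEGeneSet, set_b: DEGeneSet) -> DirectionTable:
    """Cross-tabulate up/down directions over the intersection of two DE sets.

    Association between the direction calls is tested with a two-sided
    Fisher exact test; an empty intersection yields a zero table with the
    p-value flagged undefined.
    """
    shared = set_a.members & set_b.members
    cells = {("+", "+"): 0, ("+", "-"): 0, ("-", "+"): 0, ("-", "-"): 0}
    for g in shared:
        key = (
            "+" if set_a.direction[g] > 0 else "-",
            "+" if set_b.direction[g] > 0 else "-",
        )
        cells[key] += 1
    table = np.array(
        [
            [cells[("+", "+")], cells[("+", "-")]],
            [cells[("-", "+")], cells[("-", "-")]],
        ]
    )
    if not shared:
        return DirectionTable(0, 0, 0, 0, p=float("nan"), undefined=True)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return DirectionTable(
        up_up=cells[("+", "+")],
        up_down=cells[("+", "-")],
        down_up=cells[("-", "+")],
        down_down=cells[("-", "-")],
        p=float(p),
        undefined=False,
    )


def foldchange_correlation(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    gene_filter: DEGeneSet | None = None,
    absolute: bool = False,
) -> FoldChangeCorrelation:
    """Spearman correlation of log fold-changes between two contrasts.

    Restricted to genes tested in both contrasts and, when ``gene_filter``
    is given, to its members.  With ``absolute=True`` the correlation is on
    |log FC| (magnitude concordance regardless of direction).  Ties get
    average ranks; the p-value is the large-sample approximation.
    """
    merged = pd.DataFrame(
        {"a": res_a.loc[res_a["tested"], "log_fc"], "b": res_b.loc[res_b["tested"], "log_fc"]}
    ).dropna()
    if gene_filter is not None:
        merged = merged.loc[merged.index.intersection(list(gene_filter.members))]
    if len(merged) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared genes after filtering, got {len(merged)}"
        )
    x, y = merged["a"].to_numpy(), merged["b"].to_numpy()
    if absolute:
        x, y = np.abs(x), np.abs(y)
    rho, p = stats.spearmanr(x, y)
    return FoldChangeCorrelation(
        rho=float(rho), p=float(p), n_genes=len(merged), absolute=absolute
    )


def multiway_sharing(
    sets: list[DEGeneSet], min_sets: int = 2
) -> dict:
    """Fraction of DE genes shared by at least ``min_sets`` of the sets.

    Returns a dict with ``fraction`` (|genes in >= min_sets sets| / |union|,
    0 for an empty union), ``n_union``, ``n_shared``, and for 2-3 sets the
    full Venn cell counts keyed by membership tuples such as ``(1, 0, 1)``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two DE sets")
    if min_sets < 1:
        raise ValueError("min_sets must be >= 1")
    union: set[str] = set()
    for s in sets:
        union |= s.members
    counts = {
        g: sum(1 for s in sets if g in s.members) for g in union
    }
    n_shared = sum(1 for c in counts.values() if c >= min_sets)
    out = {
        "fraction": (n_shared / len(union)) if union else 0.0,
        "n_union": len(union),
        "n_shared": n_shared,
    }
    if len(sets) <= 3:
        venn: dict[tuple[int, ...], int] = {}
        for g in union:
            key = tuple(int(g in s.members) for s in sets)
            venn[key] = venn.get(key, 0) + 1
        out["venn"] = venn
    return out


def expected_multiway_fraction(
    sizes: list[int], universe_n: int, min_sets: int = 2
) -> float:
    """Closed-form expectation of :func:`multiway_sharing`'s fraction for
    independent uniform random sets (inclusion-exclusion oracle).

    E[fraction] = E[#genes in >= min_sets sets] / E[#genes in union]; the
    ratio-of-expectations approximation is exact in the large-universe limit
    and is the quantity Monte-Carlo checks converge to.
    """
    probs = [n / universe_n for n in sizes]
    k = len(probs)
    p_ge = 0.0
    p_union = 1.0 - float(np.prod([1 - p for p in probs]))
    for m in range(min_sets, k + 1):
        for idx in combinations(range(k), m):
            term = np.prod([probs[i] if i in idx else 1 - probs[i] for i in range(k)])
            p_ge += float(term)
    return p_ge / p_union if p_union > 0 else 0.0
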