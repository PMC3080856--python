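"""Functional-category over-representation of DE genes.

One-sided hypergeometric tests per flat category label (no ontology DAG),
with the multiplicity correction style of classic gene-set tools: each raw
p-value is multiplied by the number of *testable* categories — those with
at least one DE-set gene — rather than by all categories in the map
("modified Bonferroni").  Plain Bonferroni over every category is available
as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["category_enrichment"]


def category_enrichment(
    de_set: set[str] | frozenset[str],
    universe: set[str],
    categories: pd.DataFrame,
    descriptions: dict[str, str] | None = None,
    correction: str = "modified",
) -> pd.DataFrame:
    """Hypergeometric over-representation test for every category.

    For a category with ``K`` genes in the universe of size ``N``, drawing
    the ``n = |de_set|`` DE genes at random gives the category
    ``Hypergeometric(N, K, n)`` members; ``p_raw`` is the upper-tail
    probability of at least the observed count.

    Parameters
    ----------
    de_set
        DE gene ids; must be a subset of ``universe``.
    universe
        All genes eligible for the draw (tested genes).
    categories
        Two-column DataFrame ``(gene_id, category_id)``; memberships
        outside the universe are ignored.
    correction
        ``"modified"`` multiplies p by the number of categories holding at
        least one DE gene (testable categories); ``"bonferroni"`` by all
        categories present in the universe.

    Returns a DataFrame sorted by corrected then raw p-value with columns
    ``category_id``, ``description``, ``n_in_set``, ``n_in_universe``,
    ``p_raw``, ``p_corrected``.
    """
    if correction not in ("modified", "bonferroni"):
        raise ValueError("correction must be 'modified' or 'bonferroni'")
    stray = set(de_set) - set(universe)
    if stray:
        raise ValueError(
            f"{len(stray)} DE genes absent from universe, e.g. "
            f"{sorted(stray)[:5]}"
        )
    if categories.empty:
        raise ValueError("category map is empty")
    cat = categories[categories["gene_id"].isin(universe)]
    n_univ = len(universe)
    n_draw = len(de_set)

    rows = []
    for cat_id, grp in cat.groupby("category_id", sort=True):
        members = set(grp["gene_id"])
        k = len(members & set(de_set))
        big_k = len(members)
        p_raw = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_draw))
        rows.append(
            {
                "category_id": cat_id,
                "description": (descriptions or {}).get(cat_id, ""),
                "n_in_set": k,
                "n_in_universe": big_k,
                "p_raw": p_raw,
            }
        )
    table = pd.DataFrame(rows)
    if correction == "modified":
        multiplier = int((table["n_in_set"] >= 1).sum())
    else:
        multiplier = len(table)
    table["p_corrected"] = np.minimum(1.0, table["p_raw"] * max(multiplier, 1))
    return table.sort_values(
        ["p_corrected", "p_raw"], kind="mergesort"
    ).reset_index(drop=True)
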