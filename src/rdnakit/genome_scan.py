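"""Positional analyses of differentially expressed genes along the genome.

Tests whether rDNA-responsive genes cluster anywhere on the cytological
map: per-division DE counts corrected for how many genes each division
contributes to the array (representation correction), scanning 5-division
averages, sliding megabase-window scans with an empirical null built from
random gene sets of matched size, counts of DE genes among the first genes
at heterochromatin/telomere boundaries, and chromosome-arm frequency
comparisons.

Coordinates are 0-based half-open megabase intervals; a gene belongs to a
window iff its point position lies in ``[start, start + width)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_model import DEGeneSet
from .synthetic_data import ARM_DIVISIONS

__all__ = [
    "DivisionProfile",
    "WindowScan",
    "division_profile",
    "scanning_average",
    "sliding_window_scan",
    "boundary_check",
    "arm_frequency_test",
]


@dataclass
class DivisionProfile:
    """Per-division DE counts, representation counts and their ratio.

    ``table`` has one row per cytological division with columns
    ``division``, ``arm``, ``n_de``, ``n_rep``, ``ratio`` (NaN where no
    gene is represented) and smoothed companions ``n_de_smooth``,
    ``n_rep_smooth``.
    """

    table: pd.DataFrame


@dataclass
class WindowScan:
    """Sliding-window DE density scan with empirical per-window p-values."""

    table: pd.DataFrame  # arm, start_mb, end_mb, n_de, n_total, empirical_p
    width_mb: float
    step_mb: float
    n_random: int
    seed: int
    #: empirical p of the max-over-windows count (family-wise mode)
    familywise_p: float = field(default=float("nan"))


def _divisions_frame(arms: list[str]) -> pd.DataFrame:
    rows = []
    for arm in arms:
        first, ndiv = ARM_DIVISIONS[arm]
        for d in range(first, first + ndiv):
            rows.append({"division": d, "arm": arm})
    return pd.DataFrame(rows).sort_values("division").reset_index(drop=True)


def division_profile(
    de_set: DEGeneSet,
    annotation: pd.DataFrame,
    represented: set[str] | None = None,
    smooth_divs: int = 5,
) -> DivisionProfile:
    """Bin DE and represented genes by cytological division.

    ``represented`` is the set of genes yielding analyzable data on the
    array (defaults to all annotated genes); the per-division ratio
    ``n_de / n_rep`` corrects for uneven gene density and array
    representation.  DE genes missing from the annotation raise an error
    naming the offenders.
    """
    annotated = set(annotation["gene_id"])
    missing = sorted(de_set.members - annotated)
    if missing:
        raise ValueError(
            f"{len(missing)} DE genes lack annotation, e.g. {missing[:5]}"
        )
    rep = represented if represented is not None else annotated
    ann = annotation.set_index("gene_id")
    arms = [a for a in ARM_DIVISIONS if a in set(annotation["arm"])]
    table = _divisions_frame(arms)
    de_counts = ann.loc[list(de_set.members), "division"].value_counts()
    rep_counts = ann.loc[list(rep & annotated), "division"].value_counts()
    table["n_de"] = table["division"].map(de_counts).fillna(0).astype(int)
    table["n_rep"] = table["division"].map(rep_counts).fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["ratio"] = np.where(
            table["n_rep"] > 0, table["n_de"] / table["n_rep"], np.nan
        )
    table["n_de_smooth"] = scanning_average(
        table["n_de"].to_numpy(float), table["arm"].to_numpy(), smooth_divs
    )
    table["n_rep_smooth"] = scanning_average(
        table["n_rep"].to_numpy(float), table["arm"].to_numpy(), smooth_divs
    )
    return DivisionProfile(table=table)


def scanning_average(
    series: np.ndarray,
    arms: np.ndarray | None = None,
    window_divs: int = 5,
) -> np.ndarray:
    """Centered moving average over consecutive divisions.

    Computed within each chromosome arm separately (no wraparound between
    arms); windows are truncated at arm boundaries, i.e. edge values
    average over however many of the ``window_divs`` neighbours exist.
    ``window_divs`` must be odd; 1 is the identity.
    """
    if window_divs < 1 or window_divs % 2 == 0:
        raise ValueError(f"window_divs must be odd and >= 1, got {window_divs}")
    x = np.asarray(series, dtype=float)
    if arms is None:
        arms = np.zeros(len(x))
    out = np.empty_like(x)
    half = window_divs // 2
    arms = np.asarray(arms)
    for arm in pd.unique(arms):
        idx = np.flatnonzero(arms == arm)
        vals = x[idx]
        for j in range(len(vals)):
            lo, hi = max(0, j - half), min(len(vals), j + half + 1)
            out[idx[j]] = vals[lo:hi].mean()
    return out


def _arm_windows(length: float, width: float, step: float) -> list[tuple[float, float]]:
    """Window starts every ``step`` Mb; windows truncate at the arm end so
    the arm is fully covered (step = width therefore partitions it)."""
    if length <= width:
        return [(0.0, length)]
    starts = np.arange(0.0, length, step)
    return [(float(s), float(min(s + width, length))) for s in starts if s < length]


def sliding_window_scan(
    de_set: DEGeneSet,
    annotation: pd.DataFrame,
    represented: set[str] | None = None,
    width_mb: float = 2.0,
    step_mb: float = 1.0,
    n_random: int = 1000,
    arm_lengths_mb: dict[str, float] | None = None,
    seed: int = 0,
) -> WindowScan:
    """Scan each arm with sliding windows and test DE density empirically.

    The empirical null draws ``n_random`` gene sets of the same size as the
    DE set, uniformly from the represented genes, and records each set's
    count in every window.  The per-window empirical p-value is
    ``(1 + #{random sets with count >= observed}) / (n_random + 1)`` — each
    window is compared against the random counts in the *same* window.  A
    family-wise p for the maximum count over all windows is also reported.

    Arms shorter than the window width get a single window spanning the
    whole arm.
    """
    if not 0 < step_mb <= width_mb:
        raise ValueError("require width_mb >= step_mb > 0")
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    annotated = set(annotation["gene_id"])
    rep = sorted((represented if represented is not None else annotated) & annotated)
    ann = annotation.set_index("gene_id").loc[rep]
    de_members = sorted(de_set.members & set(rep))
    n_de = len(de_members)

    if arm_lengths_mb is None:
        arm_lengths_mb = {
            arm: float(np.ceil(grp["position_mb"].max()))
            for arm, grp in annotation.groupby("arm")
        }

    # window membership matrix: genes x windows (a gene can fall in
    # width/step overlapping windows)
    windows: list[tuple[str, float, float]] = []
    for arm in [a for a in ARM_DIVISIONS if a in set(ann["arm"])]:
        for start, end in _arm_windows(arm_lengths_mb[arm], width_mb, step_mb):
            windows.append((arm, start, end))
    arm_arr = ann["arm"].to_numpy()
    pos_arr = ann["position_mb"].to_numpy()
    membership = np.zeros((len(rep), len(windows)), dtype=bool)
    for w, (arm, start, end) in enumerate(windows):
        membership[:, w] = (arm_arr == arm) & (pos_arr >= start) & (pos_arr < end)

    gene_pos = {g: i for i, g in enumerate(rep)}
    de_idx = np.array([gene_pos[g] for g in de_members], dtype=int)
    observed = membership[de_idx].sum(axis=0) if n_de else np.zeros(len(windows), int)

    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_random, len(windows)), dtype=np.int32)
    if n_de:
        for r in range(n_random):
            pick = rng.choice(len(rep), size=n_de, replace=False)
            null_counts[r] = membership[pick].sum(axis=0)
    per_window_p = (1 + (null_counts >= observed).sum(axis=0)) / (n_random + 1)
    null_max = null_counts.max(axis=1) if len(windows) else np.zeros(n_random, int)
    obs_max = int(observed.max()) if len(windows) else 0
    familywise_p = float((1 + (null_max >= obs_max).sum()) / (n_random + 1))

    table = pd.DataFrame(
        {
            "arm": [w[0] for w in windows],
            "start_mb": [w[1] for w in windows],
            "end_mb": [w[2] for w in windows],
            "n_de": observed,
            "n_total": membership.sum(axis=0),
            "empirical_p": per_window_p,
        }
    )
    return WindowScan(
        table=table,
        width_mb=width_mb,
        step_mb=step_mb,
        n_random=n_random,
        seed=seed,
        familywise_p=familywise_p,
    )


def boundary_check(
    annotation: pd.DataFrame,
    arm: str,
    de_set: DEGeneSet,
    from_end: str = "proximal",
    n_genes: int = 20,
    genome_de_rate: float | None = None,
) -> dict:
    """Count DE genes among the ``n_genes`` nearest a chromosome-arm end.

    ``from_end="proximal"`` takes the centromere-proximal end (largest
    position, adjacent to centric heterochromatin); ``"distal"`` the
    telomeric end (position 0).  Also reports the binomial probability of
    observing at least that count under the genome-wide DE rate — the null
    that boundary genes respond no differently from the rest of the genome.
    """
    if from_end not in ("proximal", "distal"):
        raise ValueError("from_end must be 'proximal' or 'distal'")
    arm_ann = annotation[annotation["arm"] == arm]
    if len(arm_ann) < n_genes:
        raise ValueError(
            f"arm {arm!r} has {len(arm_ann)} genes; need >= {n_genes}"
        )
    ordered = arm_ann.sort_values(
        "position_mb", ascending=(from_end == "distal")
    )
    nearest = ordered["gene_id"].head(n_genes)
    count = int(nearest.isin(de_set.members).sum())
    rate = (
        genome_de_rate
        if genome_de_rate is not None
        else len(de_set.members & set(annotation["gene_id"])) / len(annotation)
    )
    p_ge = float(stats.binom.sf(count - 1, n_genes, rate)) if count > 0 else 1.0
    return {
        "arm": arm,
        "from_end": from_end,
        "n_genes": n_genes,
        "de_count": count,
        "de_rate": rate,
        "p_ge": p_ge,
    }


def arm_frequency_test(
    de_set: DEGeneSet,
    annotation: pd.DataFrame,
    represented: set[str] | None = None,
) -> pd.DataFrame:
    """Compare per-arm DE frequencies with the representation expectation.

    For each arm the expected DE count is |DE| times the arm's share of
    represented genes; the relative frequency is the arm's DE rate divided
    by the DE rate on all other arms (so 1 means no arm effect).  A
    chi-square goodness-of-fit across arms tests the global null, with an
    exact binomial fallback (per-arm two-sided tests, Bonferroni-combined)
    whenever any expected count drops below 5.

    Returns one row per arm plus a ``p_overall`` column (identical across
    rows) and a ``test`` column naming the test used.
    """
    annotated = set(annotation["gene_id"])
    rep = (represented if represented is not None else annotated) & annotated
    ann = annotation[annotation["gene_id"].isin(rep)]
    de = de_set.members & rep
    n_de, n_rep = len(de), len(ann)
    if n_rep == 0:
        raise ValueError("no represented genes")

    rows = []
    for arm, grp in ann.groupby("arm", sort=True):
        rep_arm = len(grp)
        de_arm = int(grp["gene_id"].isin(de).sum())
        expected = n_de * rep_arm / n_rep
        rate_arm = de_arm / rep_arm if rep_arm else np.nan
        rep_other = n_rep - rep_arm
        de_other = n_de - de_arm
        rate_other = de_other / rep_other if rep_other else np.nan
        if rate_other is np.nan or not np.isfinite(rate_other):
            rel = np.nan
        elif rate_other > 0:
            rel = rate_arm / rate_other
        else:
            rel = np.inf if rate_arm > 0 else np.nan
        rows.append(
            {
                "arm": arm,
                "observed_de": de_arm,
                "expected_de": expected,
                "n_represented": rep_arm,
                "relative_frequency": rel,
            }
        )
    table = pd.DataFrame(rows)
    expected = table["expected_de"].to_numpy()
    observed = table["observed_de"].to_numpy()
    if (expected >= 5).all() and n_de > 0:
        chi2, p = stats.chisquare(observed, expected)
        test = "chi-square"
    else:
        # exact fallback: per-arm binomial, Bonferroni over arms
        ps = [
            stats.binomtest(
                int(o), int(nr), n_de / n_rep if n_rep else 0.0
            ).pvalue
            for o, nr in zip(observed, table["n_represented"])
        ]
        p = min(1.0, min(ps) * len(ps)) if ps else 1.0
        test = "binomial-bonferroni"
    table["p_overall"] = float(p)
    table["test"] = test
    return table
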