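"""Two-color array normalization and moderated differential expression.

The statistical path mirrors the standard two-color workflow: per-array
loess normalization of M on A, a direct-comparison (one-sample) linear model
per contrast on dye-oriented log-ratios, empirical-Bayes moderation of the
per-gene variances, two-sided p-values from the moderated t distribution,
Benjamini-Hochberg adjustment, and a permutation-based FDR estimate obtained
by re-analysing sign-randomized versions of the dataset.

Because every mutant genotype is hybridized directly against the wild-type
reference, a contrast reduces to a one-sample problem on oriented M values
(mutant minus reference); the moderated F of a single contrast is the square
of the moderated t computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InsufficientDataError",
    "NormalizedMatrix",
    "DEGeneSet",
    "PermutationFDR",
    "loess_normalize",
    "oriented_m",
    "fit_contrast",
    "moderate_and_test",
    "adjust_bh",
    "permutation_fdr",
    "call_de",
]

#: Prior degrees of freedom at or above this value are treated as infinite.
D0_CAP = 1e6


class InsufficientDataError(ValueError):
    """Raised when a stage has too few usable observations."""


@dataclass
class NormalizedMatrix:
    """Genes x hybridizations matrices of normalized M and companion A values.

    ``M = log2(red/green)`` after removal of the intensity-dependent trend;
    ``A = (log2(red) + log2(green)) / 2``.  Cells are NaN wherever the spot
    failed QC or was absent.
    """

    m: pd.DataFrame
    a: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.m.index.equals(self.a.index) or not self.m.columns.equals(
            self.a.columns
        ):
            raise ValueError("M and A matrices must share genes and hybridizations")


@dataclass(frozen=True)
class DEGeneSet:
    """A thresholded set of differentially expressed genes with directions."""

    label: str
    p_cut: float
    fdr_cut: float | None
    members: frozenset[str]
    direction: dict[str, int] = field(hash=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def loess_normalize(
    spots: pd.DataFrame,
    span: float = 0.4,
    iterations: int = 3,
    min_spots: int = 20,
) -> NormalizedMatrix:
    """Normalize per-spot intensities by loess regression of M on A.

    Within each hybridization the locally weighted linear fit of M on A is
    subtracted, removing intensity-dependent dye bias; residuals become the
    normalized M values.  Spots failing QC are excluded and reported as NaN.

    Parameters
    ----------
    spots
        Long table with columns ``gene_id``, ``hybridization_id``,
        ``intensity_red``, ``intensity_green``, ``pass_qc``.
    span
        Loess span (fraction of spots in each local window), in (0, 1].
    iterations
        Robustifying re-weighting iterations.
    min_spots
        Minimum pass-QC spots per hybridization.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0,1], got {span}")
    usable = spots[spots["pass_qc"]]
    if (usable["intensity_red"] <= 0).any() or (usable["intensity_green"] <= 0).any():
        raise ValueError("non-positive intensities among pass-QC spots")

    m_cols: dict[str, pd.Series] = {}
    a_cols: dict[str, pd.Series] = {}
    for hyb, grp in usable.groupby("hybridization_id", sort=True):
        if len(grp) < min_spots:
            raise InsufficientDataError(
                f"hybridization {hyb!r} has {len(grp)} pass-QC spots; "
                f"need >= {min_spots}"
            )
        log_r = np.log2(grp["intensity_red"].to_numpy())
        log_g = np.log2(grp["intensity_green"].to_numpy())
        m = log_r - log_g
        a = (log_r + log_g) / 2.0
        # delta collapses near-identical abscissae; standard loess speedup
        delta = 0.01 * float(np.ptp(a)) if len(a) > 200 else 0.0
        trend = lowess(
            m, a, frac=span, it=iterations, delta=delta, return_sorted=False
        )
        resid = pd.Series(m - trend, index=grp["gene_id"].to_numpy())
        # average duplicate spots of the same gene
        m_cols[hyb] = resid.groupby(level=0).mean()
        a_cols[hyb] = pd.Series(a, index=grp["gene_id"].to_numpy()).groupby(
            level=0
        ).mean()

    all_genes = pd.Index(pd.unique(spots["gene_id"])).sort_values()
    m_mat = pd.DataFrame(m_cols).reindex(index=all_genes)
    a_mat = pd.DataFrame(a_cols).reindex(index=all_genes, columns=m_mat.columns)
    m_mat.index.name = "gene_id"
    a_mat.index.name = "gene_id"
    return NormalizedMatrix(m=m_mat, a=a_mat)


def oriented_m(
    matrix: NormalizedMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """M values of the hybridizations comparing the two contrast genotypes,
    sign-oriented so that positive means higher in the mutant.

    ``contrast`` is ``(mutant, reference)``.  Hybridizations with the mutant
    in the red channel keep their sign; dye-swapped ones are negated.
    """
    mutant, reference = contrast
    forward = design[
        (design["red_genotype"] == mutant) & (design["green_genotype"] == reference)
    ]["hybridization_id"]
    reverse = design[
        (design["red_genotype"] == reference) & (design["green_genotype"] == mutant)
    ]["hybridization_id"]
    hybs = [h for h in matrix.m.columns if h in set(forward) | set(reverse)]
    if not hybs:
        raise ValueError(f"no hybridizations compare {mutant!r} to {reference!r}")
    oriented = matrix.m[hybs].copy()
    rev = [h for h in hybs if h in set(reverse)]
    oriented[rev] = -oriented[rev]
    return oriented


def fit_contrast(
    matrix: NormalizedMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    min_obs: int = 2,
) -> pd.DataFrame:
    """Per-gene summary of oriented M values for one mutant-vs-reference
    contrast: mean log fold-change, unbiased residual variance, and residual
    degrees of freedom.

    Genes with fewer than ``min_obs`` usable observations get NaN statistics
    and ``tested = False``.
    """
    if min_obs < 2:
        raise ValueError("min_obs must be >= 2")
    oriented = oriented_m(matrix, design, contrast)
    n_obs = oriented.notna().sum(axis=1)
    log_fc = oriented.mean(axis=1)
    s2 = oriented.var(axis=1, ddof=1)
    fits = pd.DataFrame(
        {
            "log_fc": log_fc,
            "s2": s2,
            "df": (n_obs - 1).clip(lower=0),
            "n_obs": n_obs,
            "tested": n_obs >= min_obs,
        }
    )
    fits.loc[~fits["tested"], ["log_fc", "s2"]] = np.nan
    fits.index.name = "gene_id"
    return fits


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Estimate the variance prior (d0, s0^2) by matching moments of log s2.

    Uses the scaled-inverse-chi-square model for gene variances: given
    residual variances ``s2`` with degrees of freedom ``df``, the
    log-variance residuals have mean digamma(df/2) - log(df/2) and variance
    trigamma(df/2) plus the prior spread trigamma(d0/2); inverting the
    trigamma gives d0, and the mean equation gives s0^2.  Returns
    ``(inf, geometric-mean-based s0^2)`` when the excess spread is
    non-positive.
    """
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 10:
        raise InsufficientDataError(
            f"need >= 10 genes with positive residual df, got {int(ok.sum())}"
        )
    s2, df = s2[ok], df[ok].astype(float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    excess = float(
        ((e - e_mean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0).mean()
    )
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_and_test(
    fits: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t test on per-gene contrast fits.

    The posterior variance shrinks each gene's ``s2`` toward the prior
    ``s0^2`` with weight ``d0`` prior degrees of freedom::

        s2_post = (d0 * s0^2 + df * s2) / (d0 + df)
        t_mod   = log_fc / sqrt(s2_post / n_obs)

    with two-sided p-values from Student's t on ``df + d0`` degrees of
    freedom.  As ``d0 -> inf`` every ``s2_post -> s0^2``; at ``d0 = 0`` the
    statistic is the ordinary one-sample t.

    ``d0`` and ``s0_sq`` may be forced; by default they are estimated from
    the data with :func:`estimate_prior`.  When every gene variance is zero
    the prior cannot be estimated: the test falls back to ``d0 = inf`` with
    a tiny positive ``s0^2`` and warns.

    Returns ``fits`` augmented with ``s2_post``, ``t_mod``, ``p``, ``p_adj``.
    """
    tested = fits["tested"].to_numpy()
    s2 = fits["s2"].to_numpy(dtype=float)
    df = fits["df"].to_numpy(dtype=float)
    n_obs = fits["n_obs"].to_numpy(dtype=float)
    log_fc = fits["log_fc"].to_numpy(dtype=float)

    if d0 is None or s0_sq is None:
        pos = tested & (s2 > 0)
        if not pos.any():
            warnings.warn(
                "all residual variances are zero; falling back to d0=inf "
                "with a machine-epsilon prior variance",
                RuntimeWarning,
                stacklevel=2,
            )
            est_d0, est_s0 = np.inf, np.finfo(float).tiny
        else:
            est_d0, est_s0 = estimate_prior(s2[tested], df[tested])
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if d0 < 0 or s0_sq < 0:
        raise ValueError("d0 and s0_sq must be non-negative")
    d0_eff = min(d0, D0_CAP)

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0_eff * s0_sq + df * s2) / (d0_eff + df)
        t_mod = log_fc / np.sqrt(s2_post / n_obs)
        # total df capped at the pooled residual df across genes: with many
        # prior df the statistic cannot be better informed than the pooled
        # variance estimate itself
        df_pooled = float(df[tested].sum())
        df_total = np.minimum(df + d0_eff, max(df_pooled, 1.0))
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = fits.copy()
    out["s2_post"] = np.where(tested, s2_post, np.nan)
    out["t_mod"] = np.where(tested, t_mod, np.nan)
    out["p"] = np.where(tested, p, np.nan)
    p_adj = np.full(len(out), np.nan)
    p_adj[tested] = adjust_bh(p[tested])
    out["p_adj"] = p_adj
    out.attrs["d0"] = float(d0)
    out.attrs["s0_sq"] = float(s0_sq)
    return out


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    matrix: NormalizedMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    min_obs: int = 2,
) -> pd.DataFrame:
    """Convenience: :func:`fit_contrast` followed by :func:`moderate_and_test`."""
    return moderate_and_test(fit_contrast(matrix, design, contrast, min_obs=min_obs))


@dataclass
class PermutationFDR:
    """Permutation-based FDR estimate for one contrast and p cutoff."""

    observed_count: int
    permuted_counts: np.ndarray
    p_cut: float
    #: mean permuted count / observed count, capped at 1; NaN when the
    #: observed count is zero (flagged by ``undefined``)
    fdr: float = field(init=False)
    undefined: bool = field(init=False)

    def __post_init__(self) -> None:
        mean_null = float(np.mean(self.permuted_counts))
        if self.observed_count == 0:
            self.fdr = float("nan")
            self.undefined = True
        else:
            self.fdr = min(1.0, mean_null / self.observed_count)
            self.undefined = False


def balanced_signs(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random sign vector with exactly half the entries negative.

    Flipping exactly ``n // 2`` (or, for odd ``n``, randomly ``n // 2`` or
    ``n // 2 + 1``) of the dye-oriented arrays re-randomizes the dye
    assignment while keeping it balanced: any common shift mu contributes
    ``mu * sum(signs) / n = 0`` (or ``mu / n``) to the permuted mean, so
    genuine effects are cancelled rather than resampled, while symmetric
    noise is unaffected.  This is the appropriate randomization for
    estimating false-discovery counts from data that contain real signal.
    """
    k = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    signs = np.ones(n)
    signs[rng.choice(n, size=k, replace=False)] = -1.0
    return signs


def permutation_fdr(
    matrix: NormalizedMatrix,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    p_cut: float = 0.001,
    n_perm: int = 50,
    min_obs: int = 2,
    seed: int = 0,
) -> PermutationFDR:
    """Estimate the FDR at ``p_cut`` from sign-randomized datasets.

    Each permutation re-randomizes the dye orientation of the arrays with a
    balanced sign flip (:func:`balanced_signs`), reruns the moderated test,
    and records the count of genes with ``p < p_cut``.  The FDR estimate is
    the mean permuted count divided by the observed count.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    oriented = oriented_m(matrix, design, contrast)
    observed = _count_de(oriented, p_cut, min_obs)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        signs = balanced_signs(rng, oriented.shape[1])
        counts[i] = _count_de(oriented * signs, p_cut, min_obs)
    return PermutationFDR(observed_count=observed, permuted_counts=counts, p_cut=p_cut)


def _count_de(oriented: pd.DataFrame, p_cut: float, min_obs: int) -> int:
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
    return int((res["p"] < p_cut).sum())


def call_de(
    results: pd.DataFrame,
    label: str,
    p_cut: float = 0.001,
    fdr_cut: float | None = 0.05,
) -> DEGeneSet:
    """Threshold moderated-test results into a differential-expression set.

    Members are the tested genes with raw ``p < p_cut`` and, when
    ``fdr_cut`` is given, BH-adjusted ``p_adj < fdr_cut``.  Directions carry
    the sign of the log fold-change.
    """
    for cut in (p_cut,) + ((fdr_cut,) if fdr_cut is not None else ()):
        if not 0 < cut <= 1:
            raise ValueError(f"threshold must be in (0,1], got {cut}")
    keep = results["tested"] & (results["p"] < p_cut)
    if fdr_cut is not None:
        keep &= results["p_adj"] < fdr_cut
    members = results.index[keep]
    direction = {
        g: (1 if results.at[g, "log_fc"] > 0 else -1) for g in members
    }
    return DEGeneSet(
        label=label,
        p_cut=p_cut,
        fdr_cut=fdr_cut,
        members=frozenset(members),
        direction=direction,
    )
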