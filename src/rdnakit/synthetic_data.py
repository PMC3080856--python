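"""Synthetic microarray and qPCR data with the structure of an rDNA-deletion
experiment.

The generator emulates a study design in which four Y chromosomes — a
wild-type and three deletion derivatives retaining roughly 87%, 85% and 46%
of the wild-type rDNA array — are each compared directly against the
wild-type on replicated, dye-balanced two-color microarrays.  A planted set
of "rDNA-sensitive" genes responds to every deletion with a sign-consistent
log2 fold-change whose magnitude scales with the severity of the deletion;
all other genes are unaffected.  Gene positions are spread over a
D. melanogaster-like cytological map (five major arms of 20 divisions each
plus the dot chromosome), so positional analyses downstream have realistic
geometry to work with.

Everything is driven by :class:`numpy.random.Generator` seeded explicitly;
identical parameters and seed give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARM_DIVISIONS",
    "DEFAULT_ARM_LENGTHS_MB",
    "DEFAULT_SEVERITY",
    "IntensityModel",
    "TruthTable",
    "generate_annotation",
    "generate_truth",
    "scale_effects",
    "assign_categories",
    "dye_balanced_design",
    "simulate_arrays",
    "simulate_qpcr",
]

#: Cytological division ranges per chromosome arm: (first division, count).
#: The five major arms carry 20 numbered divisions each; the dot chromosome
#: (arm 4) carries the final two, for 102 divisions genome-wide.
ARM_DIVISIONS: dict[str, tuple[int, int]] = {
    "X": (1, 20),
    "2L": (21, 20),
    "2R": (41, 20),
    "3L": (61, 20),
    "3R": (81, 20),
    "4": (101, 2),
}

#: Euchromatic arm lengths in megabases, close to the D. melanogaster
#: assembly so that 2-Mb windows and per-division bins behave realistically.
DEFAULT_ARM_LENGTHS_MB: dict[str, float] = {
    "X": 22.4,
    "2L": 23.0,
    "2R": 21.1,
    "3L": 24.5,
    "3R": 27.9,
    "4": 1.35,
}

#: Severity factors scaling the planted effect per genotype.  Free parameters
#: of the simulation, not biological claims: the two mild deletions get small
#: factors and the gross deletion the full base effect, so that mild DE sets
#: nest within the gross set under realistic noise.
DEFAULT_SEVERITY: dict[str, float] = {
    "wildtype": 0.0,
    "mild1": 0.30,
    "mild2": 0.35,
    "gross": 1.00,
}

#: rDNA copy number retained by each genotype, as a fraction of wild-type.
DEFAULT_COPY_FRACTION: dict[str, float] = {
    "wildtype": 1.00,
    "mild1": 0.87,
    "mild2": 0.85,
    "gross": 0.46,
}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    n_genes: int,
    arm_lengths_mb: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic gene annotation table.

    Genes are assigned to arms with probability proportional to arm length
    and placed uniformly along the arm; the cytological division is derived
    deterministically by linear binning of the position into the arm's
    division range.

    Parameters
    ----------
    n_genes
        Number of genes to place (>= 1).
    arm_lengths_mb
        Map of arm name to euchromatic length in Mb.  Arms must be a subset
        of :data:`ARM_DIVISIONS`.  Defaults to
        :data:`DEFAULT_ARM_LENGTHS_MB`.
    seed
        Random seed.

    Returns
    -------
    DataFrame with columns ``gene_id``, ``arm``, ``division``,
    ``position_mb`` (megabases from the arm's telomere).
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    lengths = dict(arm_lengths_mb) if arm_lengths_mb is not None else dict(
        DEFAULT_ARM_LENGTHS_MB
    )
    for arm, length in lengths.items():
        if arm not in ARM_DIVISIONS:
            raise ValueError(f"unknown arm {arm!r}")
        if not length > 0:
            raise ValueError(f"arm {arm!r} has non-positive length {length}")

    rng = _rng(seed)
    arms = list(lengths)
    probs = np.array([lengths[a] for a in arms], dtype=float)
    probs /= probs.sum()
    arm_idx = rng.choice(len(arms), size=n_genes, p=probs)
    pos = rng.random(n_genes)  # fraction along the arm

    arm_col = np.array(arms, dtype=object)[arm_idx]
    length_col = np.array([lengths[a] for a in arms])[arm_idx]
    position = pos * length_col

    first = np.array([ARM_DIVISIONS[a][0] for a in arms])[arm_idx]
    ndiv = np.array([ARM_DIVISIONS[a][1] for a in arms])[arm_idx]
    division = first + np.minimum((pos * ndiv).astype(int), ndiv - 1)

    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "arm": arm_col,
            "division": division,
            "position_mb": position,
        }
    )


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth of the simulation.

    Attributes
    ----------
    sensitive
        Boolean Series indexed by gene_id; True for rDNA-sensitive genes.
    base_effect
        Signed log2 fold-change of the gross-deletion contrast, indexed by
        gene_id; exactly 0 for non-sensitive genes.
    effects
        genes x genotypes DataFrame of per-contrast signed log2
        fold-changes (``base_effect`` scaled by each genotype's severity).
    severity
        The genotype -> severity map the effects were built from.
    """

    sensitive: pd.Series
    base_effect: pd.Series
    effects: pd.DataFrame
    severity: dict[str, float] = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.effects.index

    def sensitive_genes(self) -> list[str]:
        return list(self.sensitive.index[self.sensitive])


def generate_truth(
    annotation: pd.DataFrame,
    frac_sensitive: float = 0.10,
    effect_sd: float = 0.38,
    severity: Mapping[str, float] | None = None,
    max_abs_effect: float = 2.0,
    planted_cluster: tuple[str, float, float, int] | None = None,
    seed: int = 0,
) -> TruthTable:
    """Draw the planted rDNA-sensitive gene set and its effect sizes.

    A fraction ``frac_sensitive`` of genes is marked sensitive (uniformly at
    random, unless ``planted_cluster`` forces some of them into a genomic
    interval).  Each sensitive gene receives a base log2 fold-change drawn
    from a zero-mean Gaussian with ``effect_sd``, truncated at
    ``+/- max_abs_effect``; the per-genotype effect is the base effect
    multiplied by that genotype's severity factor, so signs are identical
    across genotypes and magnitudes never exceed the base magnitude.

    The default ``effect_sd`` of 0.38 makes ~87% of sensitive genes change
    expression by at most 50% (|2**effect - 1| <= 0.5), i.e. most planted
    effects are small.

    Parameters
    ----------
    planted_cluster
        Optional ``(arm, start_mb, end_mb, n_genes)``: force ``n_genes`` of
        the sensitive genes to lie in ``[start_mb, end_mb)`` on ``arm``.
    """
    if not 0 < frac_sensitive < 1:
        raise ValueError(f"frac_sensitive must be in (0,1), got {frac_sensitive}")
    if not effect_sd > 0:
        raise ValueError("effect_sd must be positive")
    if not max_abs_effect > 0:
        raise ValueError("max_abs_effect must be positive")
    sev = dict(severity) if severity is not None else dict(DEFAULT_SEVERITY)
    for g, s in sev.items():
        if not 0 <= s <= 1:
            raise ValueError(f"severity for {g!r} must be in [0,1], got {s}")

    rng = _rng(seed)
    gene_ids = pd.Index(annotation["gene_id"], name="gene_id")
    n_genes = len(gene_ids)
    n_sens = int(round(frac_sensitive * n_genes))

    sensitive = np.zeros(n_genes, dtype=bool)
    if planted_cluster is not None:
        arm, start, end, n_clust = planted_cluster
        in_interval = (
            (annotation["arm"] == arm)
            & (annotation["position_mb"] >= start)
            & (annotation["position_mb"] < end)
        ).to_numpy()
        if in_interval.sum() < n_clust:
            raise ValueError(
                f"cluster interval {arm}:{start}-{end} holds only "
                f"{int(in_interval.sum())} genes, need {n_clust}"
            )
        if n_clust > n_sens:
            raise ValueError("cluster size exceeds total sensitive count")
        inside = np.flatnonzero(in_interval)
        sensitive[rng.choice(inside, size=n_clust, replace=False)] = True
        outside = np.flatnonzero(~sensitive)
        sensitive[rng.choice(outside, size=n_sens - n_clust, replace=False)] = True
    else:
        sensitive[rng.choice(n_genes, size=n_sens, replace=False)] = True

    base = np.zeros(n_genes)
    draws = rng.normal(0.0, effect_sd, size=n_sens)
    # redraw outside the truncation bound rather than clipping, so no mass
    # piles up at +/- max_abs_effect
    bad = np.abs(draws) > max_abs_effect
    while bad.any():
        draws[bad] = rng.normal(0.0, effect_sd, size=int(bad.sum()))
        bad = np.abs(draws) > max_abs_effect
    base[sensitive] = draws

    effects = pd.DataFrame(
        {g: base * s for g, s in sev.items()}, index=gene_ids
    )
    return TruthTable(
        sensitive=pd.Series(sensitive, index=gene_ids, name="sensitive"),
        base_effect=pd.Series(base, index=gene_ids, name="base_effect"),
        effects=effects,
        severity=sev,
    )


def scale_effects(truth: TruthTable, factor: float) -> TruthTable:
    """Return a copy of ``truth`` with every effect multiplied by ``factor``.

    Used to derive the XXY-female truth table from the male one: the same
    genes respond in the same direction, attenuated by a sex factor (the
    female karyotype carries two wild-type X-linked rDNA arrays, so the
    fractional rDNA loss is smaller).  No mechanism is asserted.
    """
    return TruthTable(
        sensitive=truth.sensitive.copy(),
        base_effect=truth.base_effect * factor,
        effects=truth.effects * factor,
        severity=dict(truth.severity),
    )


def assign_categories(
    truth: TruthTable,
    n_categories: int = 50,
    baseline_prob: float = 0.02,
    enriched_category: str = "C00",
    enrichment_factor: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign flat functional-category labels to genes.

    Each (gene, category) pair is included independently with probability
    ``baseline_prob``; for **sensitive** genes the ``enriched_category``
    membership probability is multiplied by ``enrichment_factor``, planting
    one genuinely over-represented category (a stand-in for the
    mitochondrial-membrane style enrichment a real screen would find).

    Returns a two-column DataFrame ``(gene_id, category_id)``.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if not 0 < baseline_prob < 1:
        raise ValueError("baseline_prob must be in (0,1)")
    rng = _rng(seed)
    genes = truth.gene_ids.to_numpy()
    cats = [f"C{i:02d}" for i in range(n_categories)]
    if enriched_category not in cats:
        cats[0] = enriched_category
    probs = np.full((len(genes), n_categories), baseline_prob)
    enr_idx = cats.index(enriched_category)
    probs[truth.sensitive.to_numpy(), enr_idx] = min(
        1.0, baseline_prob * enrichment_factor
    )
    member = rng.random(probs.shape) < probs
    gi, ci = np.nonzero(member)
    return pd.DataFrame(
        {"gene_id": genes[gi], "category_id": np.array(cats, dtype=object)[ci]}
    )


# ---------------------------------------------------------------------------
# hybridization design
# ---------------------------------------------------------------------------

def dye_balanced_design(
    mutants: Sequence[str],
    reference: str = "wildtype",
    n_reps: int = 6,
) -> pd.DataFrame:
    """Build a direct-comparison design: each mutant genotype hybridized
    against the reference on ``n_reps`` arrays with alternating dye
    orientation (dye-swap balanced).

    Returns a DataFrame with columns ``hybridization_id``,
    ``red_genotype``, ``green_genotype``, ``replicate_index``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for mutant in mutants:
        if mutant == reference:
            raise ValueError("mutant genotype equals the reference")
        for r in range(n_reps):
            red, green = (mutant, reference) if r % 2 == 0 else (reference, mutant)
            rows.append(
                {
                    "hybridization_id": f"{mutant}_vs_{reference}_r{r}",
                    "red_genotype": red,
                    "green_genotype": green,
                    "replicate_index": r,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-color arrays
# ---------------------------------------------------------------------------

@dataclass
class IntensityModel:
    """Parameters of the spot-intensity model.

    Per gene, a baseline average log2 intensity A is drawn once from
    N(``base_mean``, ``base_sd``); each spot jitters it by N(0, ``spot_sd``).
    The dye bias added to the true log-ratio is a polynomial in (A -
    ``a_center``) with coefficients ``dye_bias_coeffs`` (constant term
    first), giving loess normalization an intensity-dependent trend to
    remove.
    """

    base_mean: float = 10.0
    base_sd: float = 1.2
    spot_sd: float = 0.15
    a_center: float = 10.0
    dye_bias_coeffs: tuple[float, ...] = (0.15, -0.06, -0.015)


def simulate_arrays(
    annotation: pd.DataFrame,
    truth: TruthTable,
    design: pd.DataFrame,
    noise_sd: float = 0.25,
    intensity_model: IntensityModel | None = None,
    qc_dropout: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-spot two-channel foreground intensities.

    For each spot the observed log-ratio is::

        M = (effect[red genotype] - effect[green genotype])
            + dye_bias(A) + Normal(0, noise_sd)

    and the two channel intensities are reconstructed as
    ``red = 2**(A + M/2)``, ``green = 2**(A - M/2)``.  A ``qc_dropout``
    fraction of spots is flagged ``pass_qc = False`` at random.

    Returns a long DataFrame with columns ``gene_id``,
    ``hybridization_id``, ``intensity_red``, ``intensity_green``,
    ``pass_qc``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= qc_dropout < 1:
        raise ValueError("qc_dropout must be in [0,1)")
    model = intensity_model if intensity_model is not None else IntensityModel()
    for col in ("red_genotype", "green_genotype"):
        unknown = set(design[col]) - set(truth.effects.columns)
        if unknown:
            raise ValueError(f"genotypes {sorted(unknown)} absent from truth table")

    rng = _rng(seed)
    genes = annotation["gene_id"].to_numpy()
    effects = truth.effects.loc[genes]
    n_genes = len(genes)
    base_a = rng.normal(model.base_mean, model.base_sd, size=n_genes)
    # polyval wants highest-order coefficient first
    poly = np.array(model.dye_bias_coeffs[::-1], dtype=float)

    frames = []
    for hyb in design.itertuples(index=False):
        m_true = (
            effects[hyb.red_genotype] - effects[hyb.green_genotype]
        ).to_numpy()
        a = base_a + (
            rng.normal(0.0, model.spot_sd, size=n_genes) if model.spot_sd > 0 else 0.0
        )
        bias = np.polyval(poly, a - model.a_center)
        m = m_true + bias
        if noise_sd > 0:
            m = m + rng.normal(0.0, noise_sd, size=n_genes)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "hybridization_id": hyb.hybridization_id,
                    "intensity_red": 2.0 ** (a + m / 2.0),
                    "intensity_green": 2.0 ** (a - m / 2.0),
                    "pass_qc": rng.random(n_genes) >= qc_dropout,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_copy_fraction: Mapping[str, float] | None = None,
    n_bio: int = 5,
    n_tech: int = 3,
    ct_sd: float = 0.05,
    base_ct: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR threshold-cycle (Ct) table for rDNA quantification.

    The expected Ct of a genotype retaining a fraction ``f`` of the
    reference rDNA copy number is ``base_ct - log2(f)`` (half the template
    costs one extra cycle at efficiency 2).  Biological replicates add
    N(0, ``ct_sd``) shared across their technical replicates; technical
    replicates add independent N(0, ``ct_sd``).

    Returns a DataFrame with columns ``genotype``, ``bio_rep``,
    ``tech_rep``, ``ct``.
    """
    fractions = (
        dict(true_copy_fraction)
        if true_copy_fraction is not None
        else dict(DEFAULT_COPY_FRACTION)
    )
    for g, f in fractions.items():
        if not 0 < f <= 1:
            raise ValueError(f"copy fraction for {g!r} must be in (0,1], got {f}")
    if n_bio < 1 or n_tech < 1:
        raise ValueError("replicate counts must be >= 1")
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")

    rng = _rng(seed)
    rows = []
    for genotype, frac in fractions.items():
        mean_ct = base_ct - np.log2(frac)
        for b in range(n_bio):
            bio_shift = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
            for t in range(n_tech):
                tech = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                rows.append(
                    {
                        "genotype": genotype,
                        "bio_rep": b,
                        "tech_rep": t,
                        "ct": mean_ct + bio_shift + tech,
                    }
                )
    return pd.DataFrame(rows)
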