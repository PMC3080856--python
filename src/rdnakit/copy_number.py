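"""Relative rDNA copy-number estimation from qPCR threshold cycles.

Uses the single-reference relative-quantification model: a sample whose
template is a fraction f of the reference reaches threshold
``log_eff(1/f)`` cycles later, so the relative quantity recovered from a
measured Ct is ``efficiency ** (Ct_ref - Ct_sample)``.  Technical
replicates are averaged within each biological replicate; biological
replicates provide the dispersion estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CopyNumberEstimate", "relative_copy_number"]


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Copy number of one genotype as percent of the reference genotype."""

    genotype: str
    percent_of_reference: float
    sd: float
    n_bio: int
    n_tech: int


def relative_copy_number(
    ct_table: pd.DataFrame,
    reference_genotype: str,
    efficiency: float = 2.0,
) -> list[CopyNumberEstimate]:
    """Estimate rDNA copy number of each genotype relative to a reference.

    Parameters
    ----------
    ct_table
        Long table with columns ``genotype``, ``bio_rep``, ``tech_rep``,
        ``ct``.  Rows with non-finite Ct are dropped with a warning.
    reference_genotype
        Genotype defining 100%.
    efficiency
        Per-cycle amplification factor, in (1, 2]; 2 is perfect doubling.

    Returns
    -------
    One :class:`CopyNumberEstimate` per genotype.  Per biological replicate
    the relative quantity is ``efficiency ** (mean reference Ct - replicate
    mean Ct)``; the genotype percent is 100 times the mean across
    biological replicates, rescaled so the reference genotype reads exactly
    100, with the standard deviation across biological replicates scaled
    the same way.
    """
    if not 1 < efficiency <= 2:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    table = ct_table.copy()
    bad = ~np.isfinite(table["ct"])
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} rows with non-finite Ct",
            RuntimeWarning,
            stacklevel=2,
        )
        table = table[~bad]
    if reference_genotype not in set(table["genotype"]):
        raise ValueError(f"reference genotype {reference_genotype!r} missing")

    # technical replicates average within biological replicate
    bio_means = (
        table.groupby(["genotype", "bio_rep"])["ct"].mean().rename("ct_bio")
    )
    tech_counts = table.groupby(["genotype", "bio_rep"])["ct"].size()
    ref_ct = float(bio_means.loc[reference_genotype].mean())

    raw: dict[str, tuple[float, float, int, int]] = {}
    for genotype, grp in bio_means.groupby(level="genotype"):
        quantities = efficiency ** (ref_ct - grp.to_numpy())
        n_bio = len(quantities)
        n_tech = int(tech_counts.loc[genotype].max())
        sd = float(np.std(quantities, ddof=1)) if n_bio > 1 else 0.0
        raw[str(genotype)] = (float(quantities.mean()), sd, n_bio, n_tech)

    # rescale so the reference genotype is 100 by construction
    ref_mean = raw[reference_genotype][0]
    estimates = []
    for genotype, (mean_q, sd_q, n_bio, n_tech) in raw.items():
        estimates.append(
            CopyNumberEstimate(
                genotype=genotype,
                percent_of_reference=100.0 * mean_q / ref_mean,
                sd=100.0 * sd_q / ref_mean,
                n_bio=n_bio,
                n_tech=n_tech,
            )
        )
    return estimates
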