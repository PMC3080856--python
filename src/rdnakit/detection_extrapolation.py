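"""Extrapolate genes escaping statistical detection in the smallest effect
decile.

Small expression changes are the hardest to detect, so the observed
histogram of relative fold-changes among significant genes is depleted in
its first bin (0-10% change) relative to the underlying effect-size
distribution.  Fitting a line to the counts in the 10-20%, 20-30%, 30-40%
and 40-50% bins and projecting it back to the first bin estimates how many
genes with <10% changes a fully powered experiment would have called; the
excess over the observed first-bin count is the estimated number of genes
escaping detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DECILE_EDGES",
    "DecileProjection",
    "decile_histogram",
    "project_first_decile",
    "estimate_missed",
]

#: Relative-change bin edges in percent: [0,10), [10,20), ..., [40,50), [50,inf)
DECILE_EDGES: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)

BIN_LABELS = ("0-10", "10-20", "20-30", "30-40", "40-50", "50+")


@dataclass(frozen=True)
class DecileProjection:
    """Linear back-projection of the first fold-change decile.

    ``slope``/``intercept`` parameterize the OLS line fitted to the counts
    of bins 10-20 ... 40-50 against bin index x = 2..5;
    ``projected_first_decile`` is the fitted value at x = 1, clamped to 0
    (``clamped`` flags when the raw projection was negative).
    """

    slope: float
    intercept: float
    projected_first_decile: float
    clamped: bool


def decile_histogram(results: pd.DataFrame, p_cut: float = 0.05) -> pd.Series:
    """Histogram of significant genes by relative expression change.

    The relative change of a gene is ``(2**|log_fc| - 1) * 100`` percent —
    the fold-change magnitude regardless of direction.  Genes with raw
    ``p < p_cut`` are binned into 10-percentage-point bins (lower edge
    inclusive) with a final open-ended 50%+ bin.

    Returns a Series indexed by bin label with integer counts.
    """
    if results.empty:
        raise ValueError("results table is empty")
    sig = results[results["tested"] & (results["p"] < p_cut)]
    pct = (2.0 ** np.abs(sig["log_fc"].to_numpy()) - 1.0) * 100.0
    counts, _ = np.histogram(pct, bins=DECILE_EDGES)
    return pd.Series(counts, index=list(BIN_LABELS), name="n_genes")


def project_first_decile(counts: np.ndarray | list[int]) -> DecileProjection:
    """Fit a line to the four bins 10-20 ... 40-50 and project bin 0-10.

    Ordinary least squares of count on bin index (x = 2, 3, 4, 5); the
    projection is the fitted value at x = 1.  Negative projections are
    clamped to zero and flagged.
    """
    y = np.asarray(counts, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"expected exactly 4 bin counts, got shape {y.shape}")
    x = np.arange(2, 6, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    raw = intercept + slope * 1.0
    clamped = raw < 0
    return DecileProjection(
        slope=float(slope),
        intercept=float(intercept),
        projected_first_decile=float(max(0.0, raw)),
        clamped=bool(clamped),
    )


def estimate_missed(
    projection: DecileProjection,
    observed_first_decile: int,
    universe_n: int | None = None,
) -> dict:
    """Estimated count of genes escaping detection in the first decile.

    ``missed = max(0, projected - observed)``.  When ``universe_n`` is
    given, also reports the estimated total affected fraction of the tested
    gene universe (observed significant genes in all bins are not included
    here — this is the first-decile correction only).
    """
    missed = max(0.0, projection.projected_first_decile - observed_first_decile)
    out = {
        "projected_first_decile": projection.projected_first_decile,
        "observed_first_decile": int(observed_first_decile),
        "estimated_missed": float(missed),
        "clamped": projection.clamped,
    }
    if universe_n:
        out["missed_fraction_of_universe"] = float(missed) / universe_n
    return out
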