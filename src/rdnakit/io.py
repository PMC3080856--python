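"""Tabular I/O: TSV readers/writers with provenance sidecars, BED export.

All tables are tab-separated with a header line.  Writers drop a sidecar
``<name>.provenance.json`` next to each file recording the generating
parameters, seed and package version, so any stage can be re-run in
isolation from its manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__all__ = [
    "write_tsv",
    "read_tsv",
    "annotation_to_bed",
    "read_annotation",
    "read_spot_table",
    "read_ct_table",
    "read_categories",
]

SPOT_COLUMNS = [
    "gene_id",
    "hybridization_id",
    "intensity_red",
    "intensity_green",
    "pass_qc",
]
ANNOTATION_COLUMNS = ["gene_id", "arm", "division", "position_mb"]
CT_COLUMNS = ["genotype", "bio_rep", "tech_rep", "ct"]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, Any] | None = None,
    seed: int | None = None,
    index: bool = False,
) -> Path:
    """Write a DataFrame as TSV and a provenance sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    from . import __version__

    sidecar = {
        "file": path.name,
        "rows": int(len(df)),
        "params": dict(params or {}),
        "seed": seed,
        "package_version": __version__,
    }
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2, default=str) + "\n"
    )
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, SPOT_COLUMNS, "spot table")
    df["pass_qc"] = df["pass_qc"].astype(bool)
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, CT_COLUMNS, "Ct table")
    return df


def read_categories(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, ["gene_id", "category_id"], "category map")
    return df


def annotation_to_bed(annotation: pd.DataFrame, path: str | Path) -> Path:
    """Write the annotation as BED (0-based half-open, 1-bp features).

    Chrom is the arm name, start the position in whole bases, the score
    column is unused (0).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    start = (annotation["position_mb"] * 1e6).astype(int)
    bed = pd.DataFrame(
        {
            "chrom": annotation["arm"],
            "start": start,
            "end": start + 1,
            "name": annotation["gene_id"],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an annotation table from TSV (with header) or BED (no header)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        from .synthetic_data import ARM_DIVISIONS

        ann = pd.DataFrame(
            {
                "gene_id": bed["name"],
                "arm": bed["chrom"],
                "position_mb": bed["start"] / 1e6,
            }
        )
        # rebuild divisions by linear binning against the observed arm extent
        divisions = []
        for arm, grp in ann.groupby("arm"):
            first, ndiv = ARM_DIVISIONS[str(arm)]
            extent = max(grp["position_mb"].max(), 1e-9)
            frac = grp["position_mb"] / extent
            div = first + (frac * ndiv).astype(int).clip(upper=ndiv - 1)
            divisions.append(div)
        ann["division"] = pd.concat(divisions).sort_index()
        return ann[ANNOTATION_COLUMNS]
    df = read_tsv(path)
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    return df
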