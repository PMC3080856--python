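"""End-to-end orchestration: simulate -> normalize -> DE -> concordance ->
genome scans -> extrapolation -> enrichment -> copy number.

One :class:`RunConfig` drives the whole chain.  A single global seed is
expanded deterministically into per-stage seeds by stage-name hashing, so
identical config and seed give byte-identical numeric outputs and any stage
can be re-run in isolation.  Every stage writes its tables as TSV under the
output directory together with a run manifest; a stage failure leaves a
``FAILED`` marker naming the stage and re-raises.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import concordance as cc
from . import copy_number as cn
from . import detection_extrapolation as dx
from . import enrichment as en
from . import expression_model as em
from . import genome_scan as gs
from . import synthetic_data as sd
from ._seeds import derive_seed
from .io import annotation_to_bed, write_tsv

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Parameters of a full simulated analysis run.

    The defaults reproduce the study design: 8073 analyzable genes, four
    Y-chromosome genotypes (wild-type, two mild rDNA deletions at 87%/85%
    copy number with severity factors 0.30/0.35, one gross deletion at 46%
    with severity 1.0), 10% of genes rDNA-sensitive with mostly small
    effects, six dye-balanced replicate hybridizations per direct
    comparison, and the threshold ladder p < {0.05, 0.01, 0.005, 0.001}
    with FDR < 0.05.
    """

    n_genes: int = 8073
    frac_sensitive: float = 0.10
    effect_sd: float = 0.38
    max_abs_effect: float = 2.0
    severity: dict[str, float] = field(
        default_factory=lambda: dict(sd.DEFAULT_SEVERITY)
    )
    copy_fraction: dict[str, float] = field(
        default_factory=lambda: dict(sd.DEFAULT_COPY_FRACTION)
    )
    reference: str = "wildtype"
    n_reps: int = 6
    noise_sd: float = 0.25
    qc_dropout: float = 0.02
    sex_attenuation: float = 0.6
    span: float = 0.4
    min_obs: int = 2
    p_cuts: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001)
    fdr_cut: float = 0.05
    de_p_cut: float = 0.001  # threshold defining the headline DE sets
    overlap_reps: int = 10_000
    window_random: int = 1000
    width_mb: float = 2.0
    step_mb: float = 1.0
    n_perm: int = 20
    n_categories: int = 50
    category_baseline: float = 0.02
    category_factor: float = 3.0
    qpcr_bio: int = 5
    qpcr_tech: int = 3
    qpcr_ct_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for cut in tuple(self.p_cuts) + (self.fdr_cut, self.de_p_cut):
            if not 0 < cut <= 1:
                raise ValueError(f"threshold {cut} outside (0, 1]")
        if self.overlap_reps < 100:
            raise ValueError("overlap_reps must be >= 100")
        if self.window_random < 100:
            raise ValueError("window_random must be >= 100")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")

    @property
    def mutants(self) -> list[str]:
        return [g for g in self.severity if g != self.reference]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "p_cuts" in data:
            data["p_cuts"] = tuple(data["p_cuts"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["p_cuts"] = list(self.p_cuts)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in dependency order and write the report bundle.

    Returns a dict of the principal in-memory results (DE sets, overlap
    tests, scan tables, projections, enrichment and copy-number tables)
    for programmatic use; all tables are also written as TSV under
    ``out_dir`` along with ``manifest.json`` and a human-readable
    ``summary.tsv`` of DE counts per contrast and threshold.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict = {}
    try:
        # ------------------------------------------------------------- simulate
        stage = "simulate"
        ann = sd.generate_annotation(
            config.n_genes, seed=derive_seed(config.seed, "annotation")
        )
        truth = sd.generate_truth(
            ann,
            frac_sensitive=config.frac_sensitive,
            effect_sd=config.effect_sd,
            severity=config.severity,
            max_abs_effect=config.max_abs_effect,
            seed=derive_seed(config.seed, "truth"),
        )
        categories = sd.assign_categories(
            truth,
            n_categories=config.n_categories,
            baseline_prob=config.category_baseline,
            enrichment_factor=config.category_factor,
            seed=derive_seed(config.seed, "categories"),
        )
        design = sd.dye_balanced_design(
            config.mutants, reference=config.reference, n_reps=config.n_reps
        )
        spots = sd.simulate_arrays(
            ann,
            truth,
            design,
            noise_sd=config.noise_sd,
            qc_dropout=config.qc_dropout,
            seed=derive_seed(config.seed, "arrays"),
        )
        params = asdict(config)
        write_tsv(ann, out / "annotation.tsv", params, config.seed)
        annotation_to_bed(ann, out / "annotation.bed")
        truth_df = pd.DataFrame(
            {"sensitive": truth.sensitive, "base_effect": truth.base_effect}
        ).join(truth.effects.add_prefix("effect_"))
        write_tsv(truth_df.reset_index(), out / "truth.tsv", params, config.seed)
        write_tsv(design, out / "design.tsv", params, config.seed)
        write_tsv(spots, out / "spots.tsv", params, config.seed)
        write_tsv(categories, out / "categories.tsv", params, config.seed)

        # ------------------------------------------------------------ normalize
        stage = "normalize"
        matrix = em.loess_normalize(spots, span=config.span)

        # ------------------------------------------------------------------- de
        stage = "de"
        contrast_results: dict[str, pd.DataFrame] = {}
        for mutant in config.mutants:
            res = em.run_contrast(
                matrix, design, (mutant, config.reference), min_obs=config.min_obs
            )
            contrast_results[mutant] = res
            write_tsv(
                res.reset_index()[
                    ["gene_id", "log_fc", "t_mod", "p", "p_adj", "n_obs"]
                ],
                out / f"contrast_{mutant}.tsv",
                params,
                config.seed,
            )
        results["contrasts"] = contrast_results

        summary_rows = []
        de_sets: dict[str, em.DEGeneSet] = {}
        for mutant, res in contrast_results.items():
            for p_cut in config.p_cuts:
                n_raw = int((res["p"] < p_cut).sum())
                n_fdr = int(
                    ((res["p"] < p_cut) & (res["p_adj"] < config.fdr_cut)).sum()
                )
                summary_rows.append(
                    {
                        "contrast": mutant,
                        "p_cut": p_cut,
                        "n_de_raw_p": n_raw,
                        "n_de_with_fdr": n_fdr,
                    }
                )
            de_sets[mutant] = em.call_de(
                res, mutant, p_cut=config.de_p_cut, fdr_cut=config.fdr_cut
            )
        summary = pd.DataFrame(summary_rows)
        write_tsv(summary, out / "summary.tsv", params, config.seed)
        results["summary"] = summary
        results["de_sets"] = de_sets

        # ---------------------------------------------------------- concordance
        stage = "concordance"
        mutants = config.mutants
        overlap_rows = []
        for i in range(len(mutants)):
            for j in range(i + 1, len(mutants)):
                a, b = mutants[i], mutants[j]
                res_a, res_b = contrast_results[a], contrast_results[b]
                tested_both = (
                    res_a.index[res_a["tested"]]
                    .intersection(res_b.index[res_b["tested"]])
                )
                k = len(de_sets[a].members & de_sets[b].members)
                test = cc.mc_overlap_null(
                    len(de_sets[a]),
                    len(de_sets[b]),
                    len(tested_both),
                    k,
                    reps=config.overlap_reps,
                    seed=derive_seed(config.seed, f"overlap:{a}:{b}"),
                )
                corr = cc.foldchange_correlation(res_a, res_b)
                overlap_rows.append(
                    {
                        "set_a": a,
                        "set_b": b,
                        "n_a": test.n1,
                        "n_b": test.n2,
                        "universe_n": test.universe_n,
                        "observed_k": test.observed_k,
                        "null_mean": test.null_mean,
                        "null_max": test.null_max,
                        "empirical_p": test.empirical_p,
                        "spearman_rho": corr.rho,
                    }
                )
        overlaps = pd.DataFrame(overlap_rows)
        write_tsv(overlaps, out / "overlaps.tsv", params, config.seed)
        results["overlaps"] = overlaps
        sharing = cc.multiway_sharing(list(de_sets.values()), min_sets=2)
        results["sharing"] = sharing

        # ---------------------------------------------------------- genome scan
        stage = "genome_scan"
        # group the three contrasts, as in the positional analyses
        union_members = frozenset().union(*(s.members for s in de_sets.values()))
        direction = {}
        for s in de_sets.values():
            direction.update(s.direction)
        grouped = em.DEGeneSet(
            label="all_deletions",
            p_cut=config.de_p_cut,
            fdr_cut=config.fdr_cut,
            members=union_members,
            direction=direction,
        )
        represented = set(
            contrast_results[mutants[0]].index[
                contrast_results[mutants[0]]["tested"]
            ]
        )
        profile = gs.division_profile(grouped, ann, represented)
        write_tsv(profile.table, out / "division_profile.tsv", params, config.seed)
        scan = gs.sliding_window_scan(
            grouped,
            ann,
            represented,
            width_mb=config.width_mb,
            step_mb=config.step_mb,
            n_random=config.window_random,
            seed=derive_seed(config.seed, "window_scan"),
        )
        write_tsv(scan.table, out / "window_scan.tsv", params, config.seed)
        arm_freq = gs.arm_frequency_test(grouped, ann, represented)
        write_tsv(arm_freq, out / "arm_frequency.tsv", params, config.seed)
        boundary = pd.DataFrame(
            [
                gs.boundary_check(ann, "X", grouped, from_end=end)
                for end in ("proximal", "distal")
            ]
        )
        write_tsv(boundary, out / "boundary_check.tsv", params, config.seed)
        results.update(
            {"profile": profile, "scan": scan, "arm_freq": arm_freq,
             "boundary": boundary, "grouped_de": grouped}
        )

        # -------------------------------------------------------- extrapolation
        stage = "extrapolation"
        proj_rows = []
        for mutant, res in contrast_results.items():
            for p_cut in (0.05, 0.01):
                hist = dx.decile_histogram(res, p_cut=p_cut)
                proj = dx.project_first_decile(hist.iloc[1:5].to_numpy())
                est = dx.estimate_missed(
                    proj, int(hist.iloc[0]), universe_n=len(represented)
                )
                proj_rows.append(
                    {"contrast": mutant, "p_cut": p_cut, **est,
                     **{f"bin_{lbl}": int(c) for lbl, c in hist.items()}}
                )
        projections = pd.DataFrame(proj_rows)
        write_tsv(projections, out / "decile_projection.tsv", params, config.seed)
        results["projections"] = projections

        # ----------------------------------------------------------- enrichment
        stage = "enrichment"
        gross = max(config.severity, key=lambda g: config.severity[g])
        enrich_set = em.call_de(
            contrast_results[gross], gross, p_cut=0.05, fdr_cut=None
        )
        enrich = en.category_enrichment(
            set(enrich_set.members) & represented, represented, categories
        )
        write_tsv(enrich, out / "enrichment.tsv", params, config.seed)
        results["enrichment"] = enrich

        # ---------------------------------------------------------- copy number
        stage = "copy_number"
        ct = sd.simulate_qpcr(
            config.copy_fraction,
            n_bio=config.qpcr_bio,
            n_tech=config.qpcr_tech,
            ct_sd=config.qpcr_ct_sd,
            seed=derive_seed(config.seed, "qpcr"),
        )
        write_tsv(ct, out / "qpcr_ct.tsv", params, config.seed)
        estimates = cn.relative_copy_number(ct, config.reference)
        cn_table = pd.DataFrame([asdict(e) for e in estimates])
        write_tsv(cn_table, out / "copy_number.tsv", params, config.seed)
        results["copy_number"] = cn_table

        # ------------------------------------------------------------- manifest
        stage = "manifest"
        from . import __version__

        manifest = {
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "seed": config.seed,
            "stage_seeds": {
                s: derive_seed(config.seed, s)
                for s in ("annotation", "truth", "categories", "arrays",
                          "window_scan", "qpcr")
            },
            "package_version": __version__,
            "n_tested_genes": len(represented),
            "multiway_sharing": {
                "fraction": sharing["fraction"],
                "n_union": sharing["n_union"],
                "n_shared": sharing["n_shared"],
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageFailure(stage, exc) from exc
    return results
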