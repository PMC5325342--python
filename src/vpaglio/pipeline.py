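"""Configuration-driven orchestration of the full analysis chain.

Stages: de -> chip-overlap -> consensus/enrich -> gsea -> subtype
(-> pharmacology), each writing TSV outputs plus a run log and a
machine-readable summary.  Defaults reproduce the study's parameter set
(q < 0.01, fold-change tiers 5/4/3/2, >= 4-of-7 support per lineage,
1 kb promoter windows); every override is echoed to the log.  All
randomness flows from one top-level seed expanded into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin import euchromatinization_matrix
from .diffexpr import all_differential_tables, pca_top_variable, rpkm
from .gsea import gsea as run_gsea
from .gsea import ranking_metric
from .integrate import family_enrichment, fc_tier_table
from .io import (
    DataValidationError,
    read_annotation,
    read_count_matrix,
    read_gmt,
    read_regions,
    write_table,
)
from .pharmacology import fit_all_curves, ic50_reduction, read_dose_response
from .subtype import classify


class PipelineConfigError(ValueError):
    """Bad or incomplete configuration (fail-fast, before any compute)."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str = ""
    meta: str = ""
    annotation: str = ""
    regions_dir: str | None = None
    gene_sets: str | None = None
    dose_response: str | None = None
    out: str = "run"
    q_thresh: float = 0.01
    fc_tiers: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0)
    min_support: int = 4
    upstream_bp: int = 1000
    min_overlap_bp: int = 1
    fc_pseudo: float = 0.5
    alternative: str = "up"
    family_set: str = "FAMILY"
    mes_set: str = "MESENCHYMAL"
    pn_set: str = "PRONEURAL"
    universe_size: int | None = None  # default: number of annotated genes
    gsea_n_perm: int = 1000
    pca_n_top: int = 1800
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "de": True,
            "chip": True,
            "consensus": True,
            "enrich": True,
            "gsea": True,
            "subtype": True,
            "pharmacology": False,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "fc_tiers" in raw:
            raw["fc_tiers"] = tuple(raw["fc_tiers"])
        if "stages" in raw:
            base = cls().stages
            base.update(raw["stages"])
            raw["stages"] = base
        return cls(**raw)

    def validate(self) -> None:
        for name in ("counts", "meta", "annotation"):
            p = getattr(self, name)
            if not p:
                raise PipelineConfigError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise PipelineConfigError(f"{name} file not found: {p}")
        if self.stages.get("chip") and not self.regions_dir:
            raise PipelineConfigError("chip stage enabled but regions_dir not set")
        if self.regions_dir and not Path(self.regions_dir).is_dir():
            raise PipelineConfigError(f"regions_dir not found: {self.regions_dir}")
        if (self.stages.get("enrich") or self.stages.get("gsea") or self.stages.get("subtype")) and not self.gene_sets:
            raise PipelineConfigError("enrich/gsea/subtype stages need a gene_sets GMT")
        if self.gene_sets and not Path(self.gene_sets).exists():
            raise PipelineConfigError(f"gene_sets file not found: {self.gene_sets}")
        if self.stages.get("pharmacology") and not self.dose_response:
            raise PipelineConfigError("pharmacology stage enabled but dose_response not set")
        if any(b >= a for a, b in zip(self.fc_tiers, self.fc_tiers[1:])):
            raise PipelineConfigError("fc_tiers must be strictly decreasing")


def _stage_seeds(seed: int, names) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, ss.spawn(len(names)))
    }


def run_all(config: PipelineConfig) -> Path:
    """Execute every enabled stage; returns the run directory.

    Re-running with identical config and inputs is bit-identical for
    deterministic stages and seed-identical for stochastic ones.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    defaults = PipelineConfig()
    for f in dataclasses.fields(PipelineConfig):
        if f.name in ("counts", "meta", "annotation", "out"):
            continue
        if getattr(config, f.name) != getattr(defaults, f.name):
            log(f"override: {f.name} = {getattr(config, f.name)!r}")

    seeds = _stage_seeds(config.seed, ["gsea"])
    log(f"vpaglio {__version__}; top-level seed {config.seed}; stage seeds {seeds}")
    summary: dict = {"config": dataclasses.asdict(config), "version": __version__, "seeds": seeds}

    counts = read_count_matrix(config.counts, config.meta)
    annotation = read_annotation(config.annotation)
    annotation.require_covers(counts.gene_ids)
    lineages = {s.cell_line: s.lineage for s in counts.samples}
    collection = read_gmt(config.gene_sets) if config.gene_sets else None
    universe_n = config.universe_size or len(annotation.gene_ids)

    de_tables = None
    if config.stages.get("de"):
        log("stage de: Audic-Claverie pairwise tests per cell line")
        try:
            de_tables = all_differential_tables(
                counts,
                fc_pseudo=config.fc_pseudo,
                alpha=config.q_thresh,
                alternative=config.alternative,
            )
        except Exception as exc:
            raise PipelineStageError("de", str(exc)) from exc
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        for line, df in de_tables.items():
            write_table(df, de_dir / f"{line}.tsv", alpha=config.q_thresh)
        n_up = {line: int((df["direction"] == "up").sum()) for line, df in de_tables.items()}
        summary["n_upregulated_per_line"] = n_up
        log(f"stage de: up-calls per line {n_up}")
        expr = rpkm(counts, annotation)
        try:
            scores, _, varexp = pca_top_variable(expr, n_top=min(config.pca_n_top, len(expr.gene_ids)))
            write_table(scores.reset_index(names="sample_id"), outdir / "pca_scores.tsv")
            summary["pca_variance_explained"] = [float(v) for v in varexp]
        except DataValidationError as exc:
            log(f"stage de: PCA skipped ({exc})")

    call_matrix = None
    if config.stages.get("chip"):
        log("stage chip-overlap: promoter euchromatinization calls")
        region_sets = {}
        for line in counts.cell_lines():
            bed = Path(config.regions_dir) / f"{line}.bed"
            if not bed.exists():
                raise PipelineStageError("chip", f"no region BED for cell line {line}: {bed}")
            region_sets[line] = read_regions(bed, sample_id=line)
        try:
            call_matrix = euchromatinization_matrix(
                region_sets,
                annotation,
                upstream_bp=config.upstream_bp,
                min_overlap_bp=config.min_overlap_bp,
            )
        except Exception as exc:
            raise PipelineStageError("chip", str(exc)) from exc
        write_table(
            call_matrix.astype(int).rename_axis("gene_id").reset_index(),
            outdir / "euchromatin_calls.tsv",
            upstream_bp=config.upstream_bp,
            min_overlap_bp=config.min_overlap_bp,
        )
        summary["euchromatin_call_rate"] = float(call_matrix.to_numpy().mean())

    if config.stages.get("consensus"):
        if de_tables is None:
            raise PipelineStageError("consensus", "de stage must be enabled")
        log("stage consensus: fold-change tier table")
        try:
            tier_df, tier_lists = fc_tier_table(
                de_tables,
                lineages,
                euchromatin=call_matrix,
                cutoffs=config.fc_tiers,
                q_thresh=config.q_thresh,
                min_support=config.min_support,
            )
        except Exception as exc:
            raise PipelineStageError("consensus", str(exc)) from exc
        write_table(tier_df, outdir / "tier_table.tsv", min_support=config.min_support)
        with open(outdir / "tier_gene_lists.json", "w") as fh:
            json.dump({str(k): v for k, v in tier_lists.items()}, fh, indent=1)
        summary["tier_table"] = tier_df.to_dict(orient="records")

        if config.stages.get("enrich"):
            family = collection[config.family_set]
            rows = []
            for cutoff in config.fc_tiers:
                for key in ("expression", "expression_and_euchromatin"):
                    if key not in tier_lists[cutoff]:
                        continue
                    res = family_enrichment(
                        tier_lists[cutoff][key], family, N=universe_n, sided="greater"
                    )
                    rows.append(
                        {
                            "fc_cutoff": cutoff,
                            "list": key,
                            "k": res.k,
                            "n": res.n,
                            "K": res.K,
                            "N": res.N,
                            "expected": res.expected,
                            "odds_ratio": res.odds_ratio,
                            "p": res.p,
                        }
                    )
            enrich_df = pd.DataFrame(rows)
            write_table(enrich_df, outdir / "family_enrichment.tsv", family=config.family_set)
            summary["family_enrichment"] = enrich_df.to_dict(orient="records")
            log(f"stage enrich: family {config.family_set} p at loosest tier "
                f"{enrich_df[enrich_df['list'] == 'expression']['p'].iloc[-1]:.3g}")

    if config.stages.get("gsea"):
        if de_tables is None:
            raise PipelineStageError("gsea", "de stage must be enabled")
        log(f"stage gsea: {config.gsea_n_perm} gene-set permutations, seed {seeds['gsea']}")
        try:
            ranked = ranking_metric(de_tables)
            gsea_df = run_gsea(
                ranked, collection, n_perm=config.gsea_n_perm, seed=seeds["gsea"]
            )
        except Exception as exc:
            raise PipelineStageError("gsea", str(exc)) from exc
        write_table(gsea_df, outdir / "gsea.tsv", n_perm=config.gsea_n_perm, seed=seeds["gsea"])
        summary["gsea"] = gsea_df.drop(columns=["leading_edge"]).to_dict(orient="records")

    if config.stages.get("subtype"):
        log("stage subtype: signature scores and paired Wilcoxon tests")
        try:
            expr = rpkm(counts, annotation)
            result = classify(expr, collection[config.mes_set], collection[config.pn_set])
        except Exception as exc:
            raise PipelineStageError("subtype", str(exc)) from exc
        write_table(result.scores, outdir / "subtype_scores.tsv")
        write_table(result.tests, outdir / "subtype_tests.tsv")
        summary["subtype_tests"] = result.tests.to_dict(orient="records")

    if config.stages.get("pharmacology"):
        log("stage pharmacology: 4PL fits and IC50 reductions")
        try:
            dose = read_dose_response(config.dose_response)
            fits = fit_all_curves(dose)
        except Exception as exc:
            raise PipelineStageError("pharmacology", str(exc)) from exc
        write_table(fits, outdir / "dose_response_fits.tsv")
        red_rows = []
        for line, grp in fits.groupby("cell_line"):
            by_status = grp.set_index("vpa_status")
            if {"naive", "treated"} <= set(by_status.index) and by_status["converged"].all():
                red_rows.append(
                    {
                        "cell_line": line,
                        "ic50_naive": by_status.loc["naive", "ic50"],
                        "ic50_treated": by_status.loc["treated", "ic50"],
                        "relative_reduction": ic50_reduction(
                            by_status.loc["naive", "ic50"], by_status.loc["treated", "ic50"]
                        ),
                    }
                )
        red_df = pd.DataFrame(red_rows)
        write_table(red_df, outdir / "ic50_reductions.tsv")
        summary["ic50_reductions"] = red_df.to_dict(orient="records")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
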