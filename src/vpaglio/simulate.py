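"""Seeded generators that emulate the study's data-generating process.

The emulated design: 14 glioma cell lines (7 adherent, 7 stem-like),
each sequenced VPA-naive and VPA-treated with no replicates; a planted
subset of genes is up-regulated by treatment in a configurable number of
lines per lineage ("support"), with a designated gene family
preferentially planted; treated-condition ChIP-enriched regions are
placed over the promoters of concordant genes; and dose-response plates
follow the 4PL model with known parameters.  Every generator is a pure
function of (parameters, seed): identical inputs give bit-identical
output, recorded in a TruthManifest serialized beside each dataset.

Counts are negative-binomial by default (dispersion 0.1), deliberately
overdispersed relative to the Poisson sampling the Audic-Claverie test
assumes, as real RNA-Seq would be; a Poisson mode exists for exact
calibration studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    DataValidationError,
    GeneAnnotation,
    GeneSetCollection,
    RegionSet,
    SampleMeta,
    write_annotation,
    write_count_matrix,
    write_gmt,
    write_regions,
)

ADHERENT_LINES = tuple(f"ADH{i}" for i in range(1, 8))
STEM_LINES = tuple(f"STEM{i}" for i in range(1, 8))


@dataclass
class TruthManifest:
    """Ground truth planted by the generators, serialized with every dataset."""

    seed: int
    params: dict
    planted_up: list[str] = field(default_factory=list)
    effects_log2: dict = field(default_factory=dict)  # gene -> planted log2 fold change
    support: dict = field(default_factory=dict)  # gene -> {lineage: [cell lines]}
    family: list[str] = field(default_factory=list)
    family_planted: list[str] = field(default_factory=list)
    euchromatin_concordant: list[str] = field(default_factory=list)
    mes_genes: list[str] = field(default_factory=list)
    pn_genes: list[str] = field(default_factory=list)
    dose_truth: dict = field(default_factory=dict)  # "line/status" -> 4PL params

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def gen_annotation(n_genes: int, n_chroms: int = 4, seed: int = 0) -> GeneAnnotation:
    """Non-overlapping gene bodies with random strands.

    Lengths are log-uniform in [500, 100000] bp; intergenic gaps of at
    least 2 kb guarantee that 1 kb promoter windows of neighbouring genes
    never overlap each other.
    """
    if n_genes < 1:
        raise DataValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(np.log(500), np.log(100_000), n_genes)).astype(np.int64)
    gaps = rng.integers(2000, 10_000, n_genes)
    strands = rng.choice(["+", "-"], n_genes)
    chroms = np.array([f"chr{(i % n_chroms) + 1}" for i in range(n_genes)])
    rows = []
    cursor = {f"chr{i+1}": 2000 for i in range(n_chroms)}
    for i in range(n_genes):
        c = chroms[i]
        start = cursor[c] + int(gaps[i])
        end = start + int(lengths[i])
        cursor[c] = end
        exonic = max(200, int(lengths[i] * rng.uniform(0.3, 0.9)))
        rows.append((f"G{i:05d}", c, start, end, strands[i], exonic))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "exonic_length"]
    ).set_index("gene_id")
    return GeneAnnotation(table=df)


def gen_counts(
    annotation: GeneAnnotation,
    seed: int = 0,
    frac_up: float = 0.02,
    effect_log2_range: tuple[float, float] = (2.0, 3.0),
    family_size: int = 30,
    n_family_planted: int = 12,
    support_per_lineage: int = 7,
    nb_dispersion: float = 0.1,
    noise: str = "nb",
    library_size_range: tuple[int, int] = (20_000_000, 50_000_000),
    planted_effects: dict[str, float] | None = None,
    planted_base_cpm_range: tuple[float, float] = (1.0, 50.0),
    n_subtype_genes: int = 50,
    lineage_boost_log2: float = 1.5,
    treatment_shift_log2: float = 0.5,
) -> tuple[CountMatrix, TruthManifest]:
    """Counts for 14 lines x {naive, vpa} with planted treatment effects.

    Planted genes gain ``2^effect`` in the treated condition of a random
    ``support_per_lineage``-of-7 subset of lines in each lineage.  The
    first ``family_size`` planted-eligible genes form the designated
    family, of which ``n_family_planted`` are planted.  Mesenchymal and
    proneural signature blocks get a lineage-specific baseline boost and
    a cross-subtype treatment shift that moves scores without flipping
    the prevailing subtype.  ``planted_effects`` overrides effect sizes
    (and membership) for specific genes.
    """
    if noise not in ("nb", "poisson"):
        raise ValueError("noise must be 'nb' or 'poisson'")
    if not 1 <= support_per_lineage <= 7:
        raise ValueError("support_per_lineage must be in 1..7")
    genes = annotation.gene_ids
    n_genes = len(genes)
    if family_size > n_genes:
        raise DataValidationError("family larger than gene count")
    rng = np.random.default_rng(seed)

    perm = rng.permutation(n_genes)
    family = sorted(genes[i] for i in perm[:family_size])
    family_planted = sorted(rng.choice(family, n_family_planted, replace=False).tolist())
    sub_pool = [genes[i] for i in perm[family_size : family_size + 2 * n_subtype_genes]]
    mes_genes = sorted(sub_pool[:n_subtype_genes])
    pn_genes = sorted(sub_pool[n_subtype_genes : 2 * n_subtype_genes])

    if planted_effects is not None:
        planted = sorted(planted_effects)
        effects = {g: float(planted_effects[g]) for g in planted}
    else:
        n_planted = max(0, int(round(frac_up * n_genes)) - n_family_planted)
        reserved = set(family) | set(mes_genes) | set(pn_genes)
        eligible = [g for g in (genes[i] for i in perm[family_size + 2 * n_subtype_genes :]) if g not in reserved]
        background = sorted(eligible[:n_planted])
        planted = sorted(set(background) | set(family_planted))
        lo, hi = effect_log2_range
        effects = {g: float(rng.uniform(lo, hi)) for g in planted}

    support: dict[str, dict[str, list[str]]] = {}
    for g in planted:
        support[g] = {
            "adherent": sorted(
                rng.choice(ADHERENT_LINES, support_per_lineage, replace=False).tolist()
            ),
            "stem": sorted(rng.choice(STEM_LINES, support_per_lineage, replace=False).tolist()),
        }

    # baseline expression in CPM; planted genes kept comfortably detectable
    base_cpm = np.exp(rng.normal(1.0, 1.5, n_genes))
    gene_index = {g: i for i, g in enumerate(genes)}
    lo_cpm, hi_cpm = planted_base_cpm_range
    for g in planted:
        base_cpm[gene_index[g]] = np.exp(rng.uniform(np.log(lo_cpm), np.log(hi_cpm)))

    samples: list[SampleMeta] = []
    for line in ADHERENT_LINES + STEM_LINES:
        lineage = "adherent" if line in ADHERENT_LINES else "stem"
        for cond in ("naive", "vpa"):
            samples.append(
                SampleMeta(
                    sample_id=f"{line}_{cond}",
                    cell_line=line,
                    lineage=lineage,
                    condition=cond,
                    library_size=int(rng.integers(*library_size_range)),
                )
            )

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    mes_idx = np.array([gene_index[g] for g in mes_genes], dtype=np.intp)
    pn_idx = np.array([gene_index[g] for g in pn_genes], dtype=np.intp)
    for j, s in enumerate(samples):
        cpm = base_cpm.copy()
        own = mes_idx if s.lineage == "adherent" else pn_idx
        other = pn_idx if s.lineage == "adherent" else mes_idx
        cpm[own] *= 2.0**lineage_boost_log2
        if s.condition == "vpa":
            cpm[other] *= 2.0**treatment_shift_log2
            for g in planted:
                if s.cell_line in support[g][s.lineage]:
                    cpm[gene_index[g]] *= 2.0 ** effects[g]
        mu = cpm * s.library_size / 1e6
        if noise == "poisson":
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / nb_dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=[s.sample_id for s in samples]),
        samples=samples,
    )
    manifest = TruthManifest(
        seed=seed,
        params={
            "frac_up": frac_up,
            "effect_log2_range": list(effect_log2_range),
            "family_size": family_size,
            "n_family_planted": n_family_planted,
            "support_per_lineage": support_per_lineage,
            "nb_dispersion": nb_dispersion,
            "noise": noise,
            "library_size_range": list(library_size_range),
            "n_subtype_genes": n_subtype_genes,
            "lineage_boost_log2": lineage_boost_log2,
            "treatment_shift_log2": treatment_shift_log2,
            "planted_base_cpm_range": list(planted_base_cpm_range),
        },
        planted_up=planted,
        effects_log2=effects,
        support=support,
        family=family,
        family_planted=family_planted,
        euchromatin_concordant=list(planted),
        mes_genes=mes_genes,
        pn_genes=pn_genes,
    )
    return cm, manifest


def gen_chip_regions(
    annotation: GeneAnnotation,
    concordant_genes,
    lines=ADHERENT_LINES + STEM_LINES,
    concordance_prob: float = 0.9,
    background_regions_per_chrom: int = 50,
    upstream_bp: int = 1000,
    seed: int = 0,
) -> dict[str, RegionSet]:
    """Treated-condition enriched regions per cell line.

    Each concordant gene's promoter receives an overlapping region with
    probability ``concordance_prob`` per line (the region lies strictly
    inside the promoter window, so with no background the resulting call
    matrix equals the planted set exactly); uniform background regions
    are added per chromosome.
    """
    if not 0 <= concordance_prob <= 1:
        raise ValueError("concordance_prob must be in [0, 1]")
    from .chromatin import promoter_windows

    rng = np.random.default_rng(seed)
    windows = {p.gene_id: p for p in promoter_windows(annotation, upstream_bp=upstream_bp)}
    chrom_len = annotation.table.groupby("chrom")["end"].max() + 10_000
    out: dict[str, RegionSet] = {}
    for line in lines:
        rows = []
        for g in concordant_genes:
            if rng.random() >= concordance_prob:
                continue
            w = windows[g]
            if w.end - w.start < 200:
                continue
            length = int(rng.integers(200, min(900, w.end - w.start) + 1))
            start = w.start + int(rng.integers(0, w.end - w.start - length + 1))
            rows.append((w.chrom, start, start + length, float(rng.uniform(1, 10))))
        for chrom, clen in chrom_len.items():
            for _ in range(background_regions_per_chrom):
                length = int(rng.integers(200, 1000))
                start = int(rng.integers(0, max(1, clen - length)))
                rows.append((chrom, start, start + length, float(rng.uniform(1, 10))))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        if df.empty:
            df = df.astype({"chrom": str, "start": np.int64, "end": np.int64, "score": float})
        out[line] = RegionSet(sample_id=line, intervals=df)
    return out


DEFAULT_DOSES = (1.0, 4.0, 16.0, 63.0, 250.0, 1000.0, 4000.0, 8000.0)


def gen_dose_response(
    curve_params: dict[tuple[str, str], dict[str, float]],
    doses=DEFAULT_DOSES,
    noise_sd: float = 5.0,
    replicates: int = 3,
    seed: int = 0,
    control_fluor: float = 1000.0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """4PL plate data: triplicate wells at 8 doses plus no-drug controls.

    ``curve_params`` maps (cell_line, vpa_status) to dicts with bottom,
    top, hill, log_ic50 (percent-of-control scale).  ``noise_sd`` is
    Gaussian noise in percent of control fluorescence.
    """
    from .pharmacology import _model

    if any(d <= 0 for d in doses):
        raise DataValidationError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for (line, status), p in sorted(curve_params.items()):
        truth[f"{line}/{status}"] = dict(p)
        for rep in range(1, replicates + 1):
            f = control_fluor * (100.0 + rng.normal(0, noise_sd)) / 100.0
            rows.append((line, status, 0.0, rep, max(f, 1.0)))
        for dose in doses:
            expected = _model(np.log10(dose), p["bottom"], p["top"], p["hill"], p["log_ic50"])
            for rep in range(1, replicates + 1):
                f = control_fluor * (expected + rng.normal(0, noise_sd)) / 100.0
                rows.append((line, status, float(dose), rep, max(f, 1.0)))
    df = pd.DataFrame(
        rows, columns=["cell_line", "vpa_status", "concentration", "replicate", "fluorescence"]
    )
    manifest = TruthManifest(
        seed=seed,
        params={"doses": list(doses), "noise_sd": noise_sd, "replicates": replicates},
        dose_truth=truth,
    )
    return df, manifest


def simulate_dataset(outdir: str | Path, seed: int = 0, **count_params) -> TruthManifest:
    """Write a complete synthetic dataset directory.

    Produces counts.tsv, meta.tsv, annotation.tsv, regions/<line>.bed,
    gene_sets.gmt (family + subtype signatures + random decoy sets),
    dose_response.csv and truth.json.  Sub-generators get seeds derived
    deterministically from the top-level seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_genes = int(count_params.pop("n_genes", 5000))
    concordance_prob = float(count_params.pop("concordance_prob", 0.9))
    background_regions = int(count_params.pop("background_regions_per_chrom", 50))
    ss = np.random.SeedSequence(seed)
    s_ann, s_cnt, s_chip, s_dose, s_decoy = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    ann = gen_annotation(n_genes, seed=s_ann)
    cm, manifest = gen_counts(ann, seed=s_cnt, **count_params)
    regions = gen_chip_regions(
        ann,
        manifest.euchromatin_concordant,
        concordance_prob=concordance_prob,
        background_regions_per_chrom=background_regions,
        seed=s_chip,
    )
    rng = np.random.default_rng(s_decoy)
    decoys = {
        f"RANDOM{i}": sorted(rng.choice(ann.gene_ids, 40, replace=False).tolist())
        for i in range(1, 4)
    }
    gmt = GeneSetCollection(
        sets={
            "FAMILY": manifest.family,
            "MESENCHYMAL": manifest.mes_genes,
            "PRONEURAL": manifest.pn_genes,
            **decoys,
        }
    )
    lines = ADHERENT_LINES[:2] + STEM_LINES[:2]
    curve_params = {}
    rngd = np.random.default_rng(s_dose)
    for line in lines:
        ic50_naive = float(rngd.uniform(800, 3000))
        reduction = float(rngd.uniform(0.3, 0.6))
        for status, ic in (("naive", ic50_naive), ("treated", ic50_naive * (1 - reduction))):
            curve_params[(line, status)] = {
                "bottom": float(rngd.uniform(0, 10)),
                "top": 100.0,
                "hill": float(rngd.uniform(-1.5, -0.7)),
                "log_ic50": float(np.log10(ic)),
            }
    dose_df, dose_manifest = gen_dose_response(curve_params, seed=s_dose)
    manifest.dose_truth = dose_manifest.dose_truth
    manifest.params.update(
        {
            "n_genes": n_genes,
            "concordance_prob": concordance_prob,
            "background_regions_per_chrom": background_regions,
            "top_seed": seed,
            "dose": dose_manifest.params,
        }
    )
    manifest.seed = seed

    write_count_matrix(cm, outdir / "counts.tsv", outdir / "meta.tsv", seed=seed)
    write_annotation(ann, outdir / "annotation.tsv", seed=seed)
    (outdir / "regions").mkdir(exist_ok=True)
    for line, rs in regions.items():
        write_regions(rs, outdir / "regions" / f"{line}.bed", seed=seed)
    write_gmt(gmt, outdir / "gene_sets.gmt")
    dose_df.to_csv(outdir / "dose_response.csv", index=False)
    manifest.to_json(outdir / "truth.json")
    return manifest
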