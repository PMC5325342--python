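"""Readers, writers and validated in-memory containers.

Tabular formats are plain TSV with a header row; interval data is BED3+
with 0-based half-open coordinates kept bit-exact (no 1-based conversion
anywhere); gene sets are standard GMT.  Writers prepend ``#`` comment
lines carrying provenance (tool version, parameters); readers skip them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__

LINEAGES = ("adherent", "stem")
CONDITIONS = ("naive", "vpa")


class DataValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: a (cell line, condition) pair with its library size."""

    sample_id: str
    cell_line: str
    lineage: str
    condition: str
    library_size: int

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise DataValidationError(
                f"sample {self.sample_id!r}: lineage must be one of {LINEAGES}, "
                f"got {self.lineage!r}"
            )
        if self.condition not in CONDITIONS:
            raise DataValidationError(
                f"sample {self.sample_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.library_size <= 0:
            raise DataValidationError(
                f"sample {self.sample_id!r}: library_size must be positive"
            )


@dataclass
class CountMatrix:
    """Integer gene x sample read counts plus per-sample metadata.

    ``library_sizes`` are total mapped reads taken from the metadata, not
    recomputed from column sums (annotated genes need not exhaust the
    library); ``read_count_matrix(..., use_column_sums=True)`` falls back
    to column sums when metadata totals are unavailable.
    """

    counts: pd.DataFrame  # genes x samples, int
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.counts.index.name = "gene_id"
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate sample ids in metadata")
        if list(self.counts.columns) != ids:
            raise DataValidationError("count matrix columns do not match sample metadata order")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        pairs = [(s.cell_line, s.condition) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise DataValidationError("duplicate (cell_line, condition) pair in metadata")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise DataValidationError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def library_sizes(self) -> pd.Series:
        return pd.Series(
            [s.library_size for s in self.samples], index=self.sample_ids, name="library_size"
        )

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "cell_line": [s.cell_line for s in self.samples],
                "lineage": [s.lineage for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "library_size": [s.library_size for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def cell_lines(self, lineage: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if lineage is None or s.lineage == lineage:
                seen.setdefault(s.cell_line, None)
        return list(seen)

    def sample_for(self, cell_line: str, condition: str) -> SampleMeta:
        for s in self.samples:
            if s.cell_line == cell_line and s.condition == condition:
                return s
        raise DataValidationError(f"no sample for cell line {cell_line!r}, condition {condition!r}")

    def require_genes(self) -> None:
        if self.counts.shape[0] == 0:
            raise DataValidationError("count matrix has no genes")


@dataclass
class GeneAnnotation:
    """Per-gene genomic coordinates (0-based half-open) and exonic length."""

    table: pd.DataFrame  # index gene_id; chrom, start, end, strand, exonic_length

    REQUIRED = ("chrom", "start", "end", "strand", "exonic_length")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise DataValidationError("duplicate gene ids in annotation")
        t = self.table
        if (t["start"] >= t["end"]).any():
            bad = t.index[t["start"] >= t["end"]].tolist()
            raise DataValidationError(f"start >= end for genes: {bad[:5]}")
        if (t["start"] < 0).any():
            raise DataValidationError("negative start coordinate in annotation")
        bad_strand = ~t["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise DataValidationError(
                f"unknown strand for genes: {t.index[bad_strand].tolist()[:5]}"
            )
        if (t["exonic_length"] <= 0).any():
            raise DataValidationError("exonic_length must be positive for every gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def require_covers(self, gene_ids: Iterable[str]) -> None:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise DataValidationError(
                f"{len(missing)} counted genes missing from annotation, e.g. {missing[:5]}"
            )


@dataclass
class RegionSet:
    """ChIP-enriched intervals for one sample; overlapping intervals are kept as-is."""

    sample_id: str
    intervals: pd.DataFrame  # chrom, start, end, score

    def __post_init__(self) -> None:
        for c in ("chrom", "start", "end"):
            if c not in self.intervals.columns:
                raise DataValidationError(f"region set missing column {c!r}")
        if "score" not in self.intervals.columns:
            self.intervals = self.intervals.assign(score=0.0)
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise DataValidationError("interval with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally with an explicit universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None
    universe_size: int | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise DataValidationError(f"gene set {name!r} has duplicate members")
        if self.universe is not None:
            uni = set(self.universe)
            for name, members in self.sets.items():
                extra = set(members) - uni
                if extra:
                    raise DataValidationError(
                        f"gene set {name!r} has members outside the universe: "
                        f"{sorted(extra)[:5]}"
                    )
            self.universe_size = len(uni)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def _provenance_header(**params) -> str:
    parts = [f"# vpaglio {__version__}"]
    for k, v in params.items():
        parts.append(f"# {k}={v}")
    return "\n".join(parts) + "\n"


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "cell_line": str})
    required = {"sample_id", "cell_line", "lineage", "condition", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=r.sample_id,
            cell_line=r.cell_line,
            lineage=r.lineage,
            condition=r.condition,
            library_size=int(r.library_size),
        )
        for r in df.itertuples()
    ]


def read_count_matrix(
    path: str | Path, meta_path: str | Path, use_column_sums: bool = False
) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids) plus metadata.

    Sample order follows the metadata file.  Counts must be non-negative
    integers; any cell violating that is reported by gene and sample.
    With ``use_column_sums=True`` the metadata library sizes are replaced
    by the per-sample column sums (for inputs lacking total mapped reads).
    """
    samples = read_sample_meta(meta_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    missing = [s.sample_id for s in samples if s.sample_id not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: samples missing from count matrix: {missing}")
    extra = [c for c in df.columns if c not in {s.sample_id for s in samples}]
    if extra:
        raise DataValidationError(f"{path}: samples in matrix missing from metadata: {extra}")
    df = df[[s.sample_id for s in samples]]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise DataValidationError(
                f"{path}: non-integer or negative count at gene {gene!r}, sample {col!r}"
            )
    df = df.astype(np.int64)
    if use_column_sums:
        samples = [
            SampleMeta(s.sample_id, s.cell_line, s.lineage, s.condition,
                       int(df[s.sample_id].sum()))
            for s in samples
        ]
    return CountMatrix(counts=df, samples=samples)


def write_count_matrix(cm: CountMatrix, path: str | Path, meta_path: str | Path, **prov) -> None:
    path, meta_path = Path(path), Path(meta_path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(**prov))
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    with open(meta_path, "w") as fh:
        fh.write(_provenance_header(**prov))
        cm.meta.to_csv(fh, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read the 6-column gene annotation TSV (gene_id chrom start end strand exonic_length)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    if "gene_id" not in df.columns:
        raise DataValidationError(f"{path}: annotation must have a gene_id column")
    return GeneAnnotation(table=df.set_index("gene_id"))


def write_annotation(ann: GeneAnnotation, path: str | Path, **prov) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(**prov))
        ann.table.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_regions(path: str | Path, sample_id: str | None = None) -> RegionSet:
    """Read BED3+ intervals; 0-based half-open coordinates are preserved exactly.

    ``track``/``browser``/``#`` lines are tolerated.  Intervals are not merged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise DataValidationError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}:{lineno}: non-numeric coordinate {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if start >= end:
                raise DataValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            rows.append((chrom, start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if df.empty:
        df = df.astype({"chrom": str, "start": np.int64, "end": np.int64, "score": float})
    return RegionSet(sample_id=sample_id or Path(path).stem, intervals=df)


def write_regions(rs: RegionSet, path: str | Path, **prov) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(sample_id=rs.sample_id, **prov))
        for r in rs.intervals.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{rs.sample_id}\t{r.score}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a line are dropped with a warning; duplicate
    set names across lines are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, members = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} had duplicate members; deduplicated",
                    stacklevel=2,
                )
            sets[name] = deduped
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False, **prov) -> None:
    """TSV writer used by every pipeline stage; prepends provenance comments."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(**prov))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)
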