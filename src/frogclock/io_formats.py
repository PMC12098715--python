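"""Readers, writers and coverage filtering for the pipeline's tabular formats.

All genomic coordinates are 0-based half-open internally. Readers validate
and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ChromatinSegmentation",
    "GeneAnnotation",
    "GenotypeMatrix",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_sample_table",
    "write_sample_table",
    "filter_by_coverage",
    "intersect_sites",
    "read_segmentation_bed",
    "write_segmentation_bed",
    "read_gene_annotation_bed",
    "write_gene_annotation_bed",
    "read_gene_annotation_gff3",
    "read_expression_table",
    "read_homolog_map",
    "read_genotype_matrix",
    "write_genotype_matrix",
]

SITE_COLUMNS = ("site_id", "chrom", "pos")
LIFE_STAGES = ("adult", "tadpole")


@dataclass
class MethylationMatrix:
    """Beta-value matrix (sites x samples) with genomic coordinates.

    ``beta`` is a DataFrame indexed by site_id with one column per sample;
    ``coverage`` (optional) has identical shape. ``chrom``/``pos`` are
    per-site arrays aligned to ``beta.index``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    beta: pd.DataFrame
    coverage: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(self.chrom) != self.n_sites or len(self.pos) != self.n_sites:
            raise ValueError("chrom/pos length does not match beta row count")
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values outside [0, 1]")
        keys = pd.MultiIndex.from_arrays([self.chrom, self.pos])
        if keys.duplicated().any():
            dup = keys[keys.duplicated()][0]
            raise ValueError(f"duplicate (chrom, pos) pair: {dup}")
        if self.coverage is not None:
            if self.coverage.shape != self.beta.shape:
                raise ValueError("coverage shape does not match beta shape")
            self.coverage = self.coverage.fillna(0).astype(np.int64)
            if (self.coverage.to_numpy() < 0).any():
                raise ValueError("negative coverage values")

    @property
    def site_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def site_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos])

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        """Restrict to sites where ``mask`` (boolean or index array) selects."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_sites:
            raise ValueError("boolean mask length does not match site count")
        return MethylationMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            beta=self.beta.iloc[mask] if mask.dtype != bool else self.beta.loc[mask],
            coverage=None
            if self.coverage is None
            else (self.coverage.iloc[mask] if mask.dtype != bool else self.coverage.loc[mask]),
        )

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_ids, "chrom": self.chrom, "pos": self.pos}
        ).set_index("site_id")


@dataclass
class ChromatinSegmentation:
    """Genome segmentation into labelled states; 0-based half-open intervals."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "state"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"segmentation requires columns {sorted(required)}")
        iv = self.intervals.sort_values(["chrom", "start"], kind="mergesort")
        if (iv["end"].to_numpy() <= iv["start"].to_numpy()).any():
            raise ValueError("segmentation interval with end <= start")
        for chrom, grp in iv.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segmentation intervals on {chrom}")
        self.intervals = iv.reset_index(drop=True)

    @property
    def states(self) -> list[str]:
        return sorted(self.intervals["state"].unique())


@dataclass
class GeneAnnotation:
    """Per-gene TSS positions (0-based) and strand."""

    genes: pd.DataFrame  # columns: gene_id, chrom, tss_pos, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss_pos", "strand"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"annotation requires columns {sorted(required)}")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in annotation")
        self.genes = self.genes.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Genotype calls (variant sites x samples, '.' = missing call)."""

    calls: pd.DataFrame
    callable_sites: int

    def __post_init__(self) -> None:
        if self.callable_sites <= 0:
            raise ValueError("callable_sites must be positive")
        if self.callable_sites < len(self.calls):
            raise ValueError("callable_sites smaller than number of variant rows")


def read_methylation_matrix(
    path: str | Path,
    coverage_path: str | Path | None = None,
    one_based: bool = False,
) -> MethylationMatrix:
    """Load a beta-value TSV (site_id, chrom, pos, then one column per sample).

    Positions are taken as 0-based unless ``one_based`` is set. Malformed rows
    are rejected with the offending line number (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    vals = df[sample_cols].to_numpy(dtype=float)
    bad = np.isnan(vals) | (vals < 0) | (vals > 1)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValueError(f"{path}: beta value outside [0, 1] at line {row + 2}")
    keys = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
    if keys.duplicated().any():
        row = int(np.argwhere(keys.duplicated())[0][0])
        raise ValueError(f"{path}: duplicate (chrom, pos) at line {row + 2}")
    pos = df["pos"].to_numpy(dtype=np.int64)
    if one_based:
        pos = pos - 1
    beta = df.set_index("site_id")[sample_cols]
    coverage = None
    if coverage_path is not None:
        cov = pd.read_csv(coverage_path, sep="\t", dtype={"chrom": str})
        cov = cov.set_index("site_id")[[c for c in cov.columns if c not in SITE_COLUMNS]]
        if list(cov.index) != list(beta.index) or list(cov.columns) != sample_cols:
            raise ValueError("coverage matrix does not align with beta matrix")
        coverage = cov
    return MethylationMatrix(
        chrom=df["chrom"].to_numpy(dtype=object), pos=pos, beta=beta, coverage=coverage
    )


def write_methylation_matrix(
    m: MethylationMatrix, path: str | Path, coverage_path: str | Path | None = None
) -> None:
    out = pd.concat(
        [pd.DataFrame({"site_id": m.site_ids, "chrom": m.chrom, "pos": m.pos}),
         m.beta.reset_index(drop=True)],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False)
    if coverage_path is not None:
        if m.coverage is None:
            raise ValueError("matrix has no coverage to write")
        cov = pd.concat(
            [pd.DataFrame({"site_id": m.site_ids, "chrom": m.chrom, "pos": m.pos}),
             m.coverage.reset_index(drop=True)],
            axis=1,
        )
        cov.to_csv(coverage_path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Load per-sample metadata (sample_id, age_years, strain, tank_id, life_stage)."""
    s = pd.read_csv(path, dtype={"sample_id": str, "strain": str, "tank_id": str})
    return validate_sample_table(s)


def validate_sample_table(s: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "age_years", "strain", "tank_id", "life_stage"}
    missing = required - set(s.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if s["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    if (s["age_years"] <= 0).any():
        raise ValueError("age_years must be positive")
    if s["tank_id"].isna().any():
        raise ValueError("tank_id must be non-null for all samples")
    if not s["life_stage"].isin(LIFE_STAGES).all():
        raise ValueError(f"life_stage must be one of {LIFE_STAGES}")
    return s.reset_index(drop=True)


def write_sample_table(s: pd.DataFrame, path: str | Path) -> None:
    s.to_csv(path, index=False)


def filter_by_coverage(
    m: MethylationMatrix, min_cov: int, min_sample_fraction: float = 1.0
) -> MethylationMatrix:
    """Keep sites with coverage >= min_cov in >= min_sample_fraction of samples.

    With ``min_sample_fraction=1.0`` a single sample below threshold drops the
    site (the strict all-samples rule used for the 100x matrix).
    """
    if m.coverage is None:
        raise ValueError(
            "matrix has no coverage; load it with read_methylation_matrix(coverage_path=...)"
        )
    frac_ok = (m.coverage.to_numpy() >= min_cov).mean(axis=1)
    return m.subset_sites(frac_ok >= min_sample_fraction)


def intersect_sites(
    a: MethylationMatrix, b: MethylationMatrix
) -> tuple[MethylationMatrix, MethylationMatrix]:
    """Restrict both matrices to their shared (chrom, pos) set, same order.

    Order follows ``a``. Used to align a clock's training site universe with
    an external test matrix before prediction.
    """
    keys_a = a.site_keys()
    keys_b = b.site_keys()
    shared = keys_a.isin(keys_b)
    if not shared.any():
        raise ValueError("matrices share no (chrom, pos) sites; clock cannot transfer")
    a_sub = a.subset_sites(np.flatnonzero(shared))
    lookup = {key: i for i, key in enumerate(keys_b)}
    order_b = np.array([lookup[key] for key in a_sub.site_keys()], dtype=np.int64)
    b_sub = b.subset_sites(order_b)
    return a_sub, b_sub


def read_segmentation_bed(path: str | Path) -> ChromatinSegmentation:
    """Read a BED4 chromatin-state segmentation (0-based half-open)."""
    iv = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "state": str},
    )
    if iv[["start", "end", "state"]].isna().any().any():
        raise ValueError(f"{path}: malformed BED4 line")
    return ChromatinSegmentation(iv)


def write_segmentation_bed(seg: ChromatinSegmentation, path: str | Path) -> None:
    seg.intervals[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_annotation_bed(path: str | Path) -> GeneAnnotation:
    """Read a BED6 gene annotation; TSS = start on '+', end-1 on '-'."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return GeneAnnotation(
        pd.DataFrame(
            {"gene_id": bed["gene_id"], "chrom": bed["chrom"],
             "tss_pos": tss.astype(np.int64), "strand": bed["strand"]}
        )
    )


def write_gene_annotation_bed(ann: GeneAnnotation, path: str | Path, width: int = 1000) -> None:
    g = ann.genes
    start = np.where(g["strand"] == "+", g["tss_pos"], g["tss_pos"] - width + 1)
    start = np.maximum(start, 0)
    end = np.where(g["strand"] == "+", g["tss_pos"] + width, g["tss_pos"] + 1)
    pd.DataFrame(
        {"chrom": g["chrom"], "start": start.astype(int), "end": end.astype(int),
         "gene_id": g["gene_id"], "score": 0, "strand": g["strand"]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotation_gff3(path: str | Path, feature: str = "gene") -> GeneAnnotation:
    """Read gene features from a GFF3 file (1-based inclusive coordinates)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line.strip()[:60]}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: gene feature without ID attribute")
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            rows.append((gene_id, chrom, tss, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_pos", "strand"])
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Gene x tissue matrix of mean log1pCP10k expression (non-negative)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if (expr.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return expr


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    hm = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "homolog_id"],
                     dtype=str)
    return hm


def read_genotype_matrix(path: str | Path, callable_sites: int | None = None) -> GenotypeMatrix:
    """Read a genotype TSV (sites x samples, '.' missing).

    The callable-site count is taken from a leading ``#callable_sites=N``
    comment line, or from the argument (which overrides the header).
    """
    header_callable = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#callable_sites="):
            header_callable = int(first.strip().split("=", 1)[1])
    calls = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    n_callable = callable_sites if callable_sites is not None else header_callable
    if n_callable is None:
        raise ValueError(
            "callable_sites not given and no '#callable_sites=' header present"
        )
    return GenotypeMatrix(calls=calls, callable_sites=n_callable)


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#callable_sites={g.callable_sites}\n")
        g.calls.to_csv(fh, sep="\t")
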