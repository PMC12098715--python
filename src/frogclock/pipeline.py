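"""End-to-end pipeline orchestration from a single TOML config.

Stage order mirrors the analysis: coverage filter -> artifact filter ->
clock CV -> age association -> chromatin enrichment -> proximal expression
-> genotype divergence. Every stage writes a TSV and the run writes a JSON
manifest (parameters, seeds, per-stage row counts) so that reruns with the
same config and seed are reproducible.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .age_association import ALPHA, select_significant, spearman_with_age
from .artifact_filter import (
    DELTA_BIC_THRESHOLD,
    MIN_BETA_CUTOFF,
    apply_artifact_filter,
    flag_artifact_sites,
)
from .chromatin_enrichment import assign_states, state_enrichment
from .clock import loo_cv, loto_cv, shuffled_loto_cv
from .genotype_divergence import pairwise_divergence, tank_average
from .io_formats import (
    filter_by_coverage,
    read_gene_annotation_bed,
    read_gene_annotation_gff3,
    read_expression_table,
    read_genotype_matrix,
    read_homolog_map,
    read_methylation_matrix,
    read_sample_table,
    read_segmentation_bed,
    write_methylation_matrix,
)
from .proximal_expression import build_proximal_gene_set, compare_expression

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = (
    "coverage_filter",
    "artifact_filter",
    "clock_cv",
    "age_association",
    "chromatin_enrichment",
    "proximal_expression",
    "genotype_divergence",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Defaults follow the study's stated parameters: 100x coverage in all
    samples, delta-BIC 90 with min-beta 0.006, l1_ratio 0.5, BH alpha 0.001,
    5 kb TSS cutoff, 5 shuffled-LOTO repeats.
    """

    methylation_path: Path
    coverage_path: Path
    samples_path: Path
    output_dir: Path
    segmentation_path: Path | None = None
    annotation_path: Path | None = None
    expression_path: Path | None = None
    homolog_path: Path | None = None
    genotype_path: Path | None = None
    min_coverage: int = 100
    min_sample_fraction: float = 1.0
    delta_bic: float = DELTA_BIC_THRESHOLD
    min_beta: float = MIN_BETA_CUTOFF
    cv_schemes: tuple[str, ...] = ("loo", "loto")
    shuffled_repeats: int = 5
    log_age: bool = False
    alpha: float = ALPHA
    enrichment_background_min_coverage: int = 10
    max_tss_distance: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = Path(path).parent

        def _p(key, required=False):
            if key not in raw or raw[key] is None:
                if required:
                    raise ValueError(f"config missing required path '{key}'")
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        cfg = cls(
            methylation_path=_p("methylation_path", required=True),
            coverage_path=_p("coverage_path", required=True),
            samples_path=_p("samples_path", required=True),
            output_dir=_p("output_dir", required=True),
            segmentation_path=_p("segmentation_path"),
            annotation_path=_p("annotation_path"),
            expression_path=_p("expression_path"),
            homolog_path=_p("homolog_path"),
            genotype_path=_p("genotype_path"),
            min_coverage=int(raw.get("min_coverage", 100)),
            min_sample_fraction=float(raw.get("min_sample_fraction", 1.0)),
            delta_bic=float(raw.get("delta_bic", DELTA_BIC_THRESHOLD)),
            min_beta=float(raw.get("min_beta", MIN_BETA_CUTOFF)),
            cv_schemes=tuple(raw.get("cv_schemes", ["loo", "loto"])),
            shuffled_repeats=int(raw.get("shuffled_repeats", 5)),
            log_age=bool(raw.get("log_age", False)),
            alpha=float(raw.get("alpha", ALPHA)),
            max_tss_distance=int(raw.get("max_tss_distance", 5000)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("methylation_path", "coverage_path", "samples_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        optional = (
            "segmentation_path", "annotation_path", "expression_path",
            "homolog_path", "genotype_path",
        )
        for name in optional:
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        unknown = set(self.cv_schemes) - {"loo", "loto", "shuffled_loto"}
        if unknown:
            raise ValueError(f"unknown CV scheme(s): {sorted(unknown)}")

    @property
    def enrichment_enabled(self) -> bool:
        return self.segmentation_path is not None

    @property
    def expression_enabled(self) -> bool:
        return all(
            p is not None
            for p in (self.annotation_path, self.expression_path, self.homolog_path)
        )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the output directory.

    A stage failure aborts the run with the stage name in the error; outputs
    of completed stages are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
        },
        "stages": {},
    }
    stage = None
    try:
        stage = "coverage_filter"
        m = read_methylation_matrix(config.methylation_path, config.coverage_path)
        samples = read_sample_table(config.samples_path)
        m_cov = filter_by_coverage(m, config.min_coverage, config.min_sample_fraction)
        write_methylation_matrix(m_cov, out / "01_coverage_filtered.tsv")
        manifest["stages"][stage] = {
            "sites_in": m.n_sites, "sites_out": m_cov.n_sites,
        }

        stage = "artifact_filter"
        fits = flag_artifact_sites(
            m_cov, config.delta_bic, config.min_beta, seed=config.seed
        )
        m_clean = apply_artifact_filter(m_cov, fits)
        fits.table.to_csv(out / "02_artifact_fits.tsv", sep="\t")
        write_methylation_matrix(m_clean, out / "02_artifact_filtered.tsv")
        manifest["stages"][stage] = {
            "sites_in": m_cov.n_sites,
            "sites_out": m_clean.n_sites,
            "flagged": int(fits.flagged.sum()),
        }

        stage = "clock_cv"
        cv_rows = []
        preds = []
        for scheme in config.cv_schemes:
            if scheme == "loo":
                results = [loo_cv(m_clean, samples, config.log_age, seed=config.seed)]
            elif scheme == "loto":
                results = [loto_cv(m_clean, samples, config.log_age, seed=config.seed)]
            else:
                results = shuffled_loto_cv(
                    m_clean, samples, config.shuffled_repeats,
                    config.log_age, seed=config.seed,
                )
            for rep, res in enumerate(results):
                cv_rows.append(
                    {
                        "scheme": res.scheme, "repeat": rep,
                        "medae_years": res.medae, "pearson_r": res.pearson_r,
                    }
                )
                p = res.predictions.copy()
                p["scheme"] = res.scheme
                p["repeat"] = rep
                preds.append(p)
        pd.concat(preds).to_csv(out / "03_clock_predictions.tsv", sep="\t")
        cv_table = pd.DataFrame(cv_rows)
        cv_table.to_csv(out / "03_clock_metrics.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "schemes": list(config.cv_schemes),
            "metrics": cv_table.to_dict(orient="records"),
        }

        stage = "age_association"
        stats_ = spearman_with_age(m_clean, samples, alpha=config.alpha)
        pos_sites, neg_sites = select_significant(stats_)
        stats_.table.to_csv(out / "04_site_stats.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_positive": len(pos_sites), "n_negative": len(neg_sites),
        }

        if config.enrichment_enabled:
            stage = "chromatin_enrichment"
            seg = read_segmentation_bed(config.segmentation_path)
            # Background: all artifact-filtered sites at the (lower)
            # enrichment coverage threshold.
            m_bg = filter_by_coverage(
                m, config.enrichment_background_min_coverage, 1.0
            )
            bg_keys = m_bg.site_keys()
            keep = m_clean.site_keys().isin(bg_keys)
            background = list(m_clean.site_ids[keep])
            assignment = pd.Series(
                assign_states(m_clean.chrom, m_clean.pos, seg), index=m_clean.site_ids
            )
            tables = []
            for direction, sel in (("positive", pos_sites), ("negative", neg_sites)):
                et = state_enrichment(sel, background, assignment, direction)
                t = et.table.reset_index()
                t.insert(0, "direction", direction)
                tables.append(t)
            enrich = pd.concat(tables, ignore_index=True)
            enrich.to_csv(out / "05_enrichment.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"rows": len(enrich)}

        if config.expression_enabled:
            stage = "proximal_expression"
            ann_path = Path(config.annotation_path)
            ann = (
                read_gene_annotation_gff3(ann_path)
                if ann_path.suffix in (".gff3", ".gff")
                else read_gene_annotation_bed(ann_path)
            )
            expr = read_expression_table(config.expression_path)
            homologs = read_homolog_map(config.homolog_path)
            sites_frame = pd.DataFrame(
                {"site_id": m_clean.site_ids, "chrom": m_clean.chrom, "pos": m_clean.pos}
            )
            sets = []
            for direction, sel in (("positive", pos_sites), ("negative", neg_sites)):
                cpgs = sites_frame[sites_frame["site_id"].isin(sel)]
                sets.append(
                    build_proximal_gene_set(
                        cpgs, ann, homologs, expr.index, direction,
                        config.max_tss_distance,
                    )
                )
            comparison = compare_expression(sets, expr)
            comparison.table.to_csv(out / "06_expression.tsv", sep="\t")
            manifest["stages"][stage] = {
                "n_genes": {gs.direction: len(gs.genes) for gs in sets},
            }

        if config.genotype_path is not None:
            stage = "genotype_divergence"
            g = read_genotype_matrix(config.genotype_path)
            div = pairwise_divergence(g)
            div.matrix.to_csv(out / "07_divergence_samples.tsv", sep="\t")
            tanks = tank_average(div, samples)
            tanks.to_csv(out / "07_divergence_tanks.tsv", sep="\t")
            manifest["stages"][stage] = {"n_samples": len(div.matrix)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
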