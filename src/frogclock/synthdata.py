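"""Synthetic frog cohorts with the statistical structure the analysis assumes.

The generator emulates a colony in which each tank houses frogs of a single
age and strain (so tank, age and strain are confounded), with per-site
methylation trajectories on the logit scale, beta-distributed measurement
noise, trimodal genotype-artifact sites driven by a segregating C-to-T
allele, and negative-binomial read coverage. All outputs carry full ground
truth so that every downstream stage can be scored against planted effects.

Randomness is organised as one child stream per output object, derived from
the master seed, so that e.g. changing the number of sites never perturbs
the generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    ChromatinSegmentation,
    GeneAnnotation,
    GenotypeMatrix,
    MethylationMatrix,
    write_gene_annotation_bed,
    write_genotype_matrix,
    write_methylation_matrix,
    write_sample_table,
    write_segmentation_bed,
)

__all__ = [
    "SynthConfig",
    "TruthLabels",
    "ContextFixtures",
    "generate_cohort",
    "generate_methylation",
    "generate_context_fixtures",
    "STATE_NAMES",
]

# Stream ids: one independent RNG per output object.
_STREAM_COHORT = 0
_STREAM_SITES = 1
_STREAM_METH = 2
_STREAM_GENO = 3
_STREAM_CONTEXT = 4

# Chromatin-state vocabulary loosely following embryo ChromHMM annotations.
STATE_NAMES = [
    "quiescent", "heterochromatin1", "heterochromatin2", "repetitive",
    "bivalent_low", "bivalent_high", "strongly_transcribed", "transcribed",
    "enhancer", "active_promoter", "poised_promoter", "polycomb",
    "insulator", "flanking_tss", "low_signal",
]

_SITE_SPACING = 10_000  # bp between consecutive synthetic CpGs
_N_CHROMS = 10

# Trimodal artifact-site modes (CC / CT / TT) and their jitter SDs. The TT
# mode must stay below the vanishing-methylation cutoff (0.006) used by the
# artifact filter, so its jitter is much tighter than the other modes'.
_ARTIFACT_MODES = {"CC": 0.95, "CT": 0.5, "TT": 0.0005}
_ARTIFACT_SD = {"CC": 0.01, "CT": 0.01, "TT": 0.001}
_TT_CEILING = 0.0059

_BETA_EPS = 1e-6


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design: 34 tanks with a typical 6 frogs each,
    ages spanning 0.25-10.9 years, a minority of sites trending with age at
    ~0.2 logit-units/year, and beta noise at concentration phi = 50.
    """

    n_tanks: int = 34
    frogs_per_tank: int | tuple[int, ...] = 6
    age_range: tuple[float, float] = (0.25, 10.9)
    n_sites: int = 2000
    frac_pos: float = 0.1
    frac_neg: float = 0.1
    frac_artifact: float = 0.05
    slope_scale: float = 0.2        # logit-units per year
    baseline_sd: float = 1.0        # logit-units
    tank_sd: float = 0.0            # logit-units, SD of per-(tank, site) shift
    precision: float = 50.0         # beta-distribution concentration phi
    t_allele_freq: float = 0.5      # mean strain-level T-allele frequency
    coverage_mean: float = 300.0
    coverage_dispersion: float = 5.0
    min_coverage: int = 100         # floor applied to generated depths
    seed: int = 0
    n_strains: int = 4
    tadpole_age_years: float = 0.0  # samples at or below this age are tadpoles
    # Context-fixture design: planted chromatin-state enrichment of
    # positive-class sites and down-scaled expression of their proximal genes.
    enriched_state: str = "bivalent_low"
    frac_pos_in_enriched: float = 0.5
    background_in_enriched: float = 0.1
    expression_scale: float = 0.5   # multiplier on planted proximal genes
    plant_effects: bool = True
    n_tissues: int = 8
    callable_sites: int = 1_003_455

    def validate(self) -> None:
        if self.n_tanks < 1:
            raise ValueError("n_tanks must be >= 1")
        if isinstance(self.frogs_per_tank, int):
            if self.frogs_per_tank < 1:
                raise ValueError("frogs_per_tank must be >= 1")
        else:
            if len(self.frogs_per_tank) != self.n_tanks:
                raise ValueError("frogs_per_tank list length must equal n_tanks")
            if any(k < 1 for k in self.frogs_per_tank):
                raise ValueError("frogs_per_tank entries must be >= 1")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ValueError("age_range must satisfy 0 < min <= max")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("frac_pos", "frac_neg", "frac_artifact", "t_allele_freq",
                     "frac_pos_in_enriched", "background_in_enriched"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_pos + self.frac_neg + self.frac_artifact > 1 + 1e-12:
            raise ValueError("frac_pos + frac_neg + frac_artifact must be <= 1")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean and coverage_dispersion must be > 0")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthLabels:
    """Ground truth for a generated methylation matrix."""

    site_class: pd.Series          # site_id -> {positive, negative, null, artifact}
    true_slope: pd.Series          # site_id -> logit-units/year (0 for non-trend)
    genotype: pd.DataFrame         # artifact site_id x sample -> {CC, CT, TT}

    def __post_init__(self) -> None:
        valid = {"positive", "negative", "null", "artifact"}
        if not set(self.site_class.unique()) <= valid:
            raise ValueError(f"site_class values must be in {valid}")
        artifacts = set(self.site_class.index[self.site_class == "artifact"])
        if set(self.genotype.index) != artifacts:
            raise ValueError("genotype rows must be exactly the artifact sites")


@dataclass
class ContextFixtures:
    """Segmentation, annotation, expression, homology and genotype fixtures."""

    segmentation: ChromatinSegmentation
    annotation: GeneAnnotation
    expression: pd.DataFrame
    homolog_map: pd.DataFrame
    genotypes: GenotypeMatrix
    site_state: pd.Series          # site_id -> planted state label
    planted_genes: list[str]       # expression-namespace ids with scaled expression


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate the per-sample metadata table.

    Every frog in a tank shares that tank's age and strain; tank ages are
    drawn uniformly on ``age_range``.
    """
    config.validate()
    rng = config.rng(_STREAM_COHORT)
    if isinstance(config.frogs_per_tank, int):
        sizes = np.full(config.n_tanks, config.frogs_per_tank, dtype=int)
    else:
        sizes = np.asarray(config.frogs_per_tank, dtype=int)
    tank_ages = rng.uniform(*config.age_range, size=config.n_tanks)
    tank_strains = rng.integers(0, config.n_strains, size=config.n_tanks)
    rows = []
    frog = 0
    for t in range(config.n_tanks):
        for _ in range(sizes[t]):
            rows.append(
                {
                    "sample_id": f"F{frog:04d}",
                    "age_years": tank_ages[t],
                    "strain": f"S{tank_strains[t]:02d}",
                    "tank_id": f"T{t:03d}",
                    "life_stage": "tadpole"
                    if tank_ages[t] <= config.tadpole_age_years
                    else "adult",
                }
            )
            frog += 1
    return pd.DataFrame(rows)


def _allocate_site_classes(config: SynthConfig, rng: np.random.Generator):
    """Deterministic class counts (rounded), shuffled across genomic order."""
    n = config.n_sites
    n_pos = int(round(config.frac_pos * n))
    n_neg = int(round(config.frac_neg * n))
    n_art = int(round(config.frac_artifact * n))
    if n_pos + n_neg + n_art > n:
        raise ValueError("rounded class counts exceed n_sites")
    classes = np.array(
        ["positive"] * n_pos + ["negative"] * n_neg + ["artifact"] * n_art
        + ["null"] * (n - n_pos - n_neg - n_art),
        dtype=object,
    )
    rng.shuffle(classes)
    return classes


def _site_coordinates(n_sites: int):
    per_chrom = int(np.ceil(n_sites / _N_CHROMS))
    idx = np.arange(n_sites)
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in idx], dtype=object)
    pos = ((idx % per_chrom) + 1) * _SITE_SPACING
    return chrom, pos.astype(np.int64)


def generate_methylation(
    samples: pd.DataFrame, config: SynthConfig
) -> tuple[MethylationMatrix, TruthLabels]:
    """Generate beta values, coverage and ground-truth labels for a cohort.

    Trend sites follow mean mu_ij = expit(b0_j + b1_j * age_i + u_{t(i),j})
    with Beta(mu*phi, (1-mu)*phi) noise; artifact sites emit genotype-driven
    trimodal values; coverage is negative-binomial floored at min_coverage.
    """
    config.validate()
    if len(samples) == 0:
        raise ValueError("samples table is empty")
    if config.n_sites == 0:
        raise ValueError("n_sites must be positive")

    site_rng = config.rng(_STREAM_SITES)
    meth_rng = config.rng(_STREAM_METH)
    geno_rng = config.rng(_STREAM_GENO)

    n_sites, n_samples = config.n_sites, len(samples)
    classes = _allocate_site_classes(config, site_rng)
    chrom, pos = _site_coordinates(n_sites)
    site_ids = pd.Index([f"s{i:06d}" for i in range(n_sites)], name="site_id")

    ages = samples["age_years"].to_numpy(dtype=float)
    tanks = samples["tank_id"].to_numpy()
    tank_codes, tank_index = pd.factorize(tanks)
    strains = samples["strain"].to_numpy()
    strain_codes, strain_index = pd.factorize(strains)

    # Per-site trajectory parameters on the logit scale.
    sign = np.where(classes == "positive", 1.0, np.where(classes == "negative", -1.0, 0.0))
    magnitude = site_rng.uniform(0.5, 1.5, size=n_sites) * config.slope_scale
    slope = sign * magnitude
    mean_age = ages.mean()
    baseline = site_rng.normal(-slope * mean_age, config.baseline_sd)

    tank_effect = (
        meth_rng.normal(0.0, config.tank_sd, size=(len(tank_index), n_sites))
        if config.tank_sd > 0
        else np.zeros((len(tank_index), n_sites))
    )

    mu = expit(
        baseline[None, :] + np.outer(ages, slope) + tank_effect[tank_codes, :]
    )  # samples x sites
    phi = config.precision
    beta_vals = meth_rng.beta(mu * phi, (1.0 - mu) * phi)

    # Artifact sites: strain-level T-allele frequency -> Hardy-Weinberg
    # genotypes -> trimodal methylation replacing the trend values.
    artifact_idx = np.flatnonzero(classes == "artifact")
    genotype = pd.DataFrame(
        index=site_ids[artifact_idx], columns=samples["sample_id"], dtype=object
    )
    if artifact_idx.size:
        q = np.clip(
            geno_rng.normal(
                config.t_allele_freq, 0.15, size=(len(strain_index), artifact_idx.size)
            ),
            0.05, 0.95,
        )  # strains x artifact sites
        q_sample = q[strain_codes, :]  # samples x artifact sites
        u = geno_rng.uniform(size=(n_samples, artifact_idx.size))
        # genotype code: 0=TT (prob q^2), 1=CT (2pq), 2=CC (p^2)
        p_tt = q_sample**2
        p_ct = 2 * q_sample * (1 - q_sample)
        code = np.where(u < p_tt, 0, np.where(u < p_tt + p_ct, 1, 2))
        labels = np.array(["TT", "CT", "CC"], dtype=object)
        genotype.iloc[:, :] = labels[code].T

        vals = np.empty_like(u)
        for g, gi in (("TT", 0), ("CT", 1), ("CC", 2)):
            mask = code == gi
            draw = geno_rng.normal(_ARTIFACT_MODES[g], _ARTIFACT_SD[g], size=mask.sum())
            if g == "TT":
                draw = np.clip(np.abs(draw), _BETA_EPS, _TT_CEILING)
            vals[mask] = draw
        beta_vals[:, artifact_idx] = vals
        slope[artifact_idx] = 0.0

    beta_vals = np.clip(beta_vals, _BETA_EPS, 1.0 - _BETA_EPS)

    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    coverage = meth_rng.negative_binomial(nb_n, nb_p, size=(n_samples, n_sites))
    coverage = np.maximum(coverage, config.min_coverage)

    matrix = MethylationMatrix(
        chrom=chrom,
        pos=pos,
        beta=pd.DataFrame(beta_vals.T, index=site_ids, columns=samples["sample_id"]),
        coverage=pd.DataFrame(
            coverage.T, index=site_ids, columns=samples["sample_id"]
        ),
    )
    truth = TruthLabels(
        site_class=pd.Series(classes, index=site_ids, name="site_class"),
        true_slope=pd.Series(slope, index=site_ids, name="true_slope"),
        genotype=genotype,
    )
    return matrix, truth


def _planted_state_assignment(
    classes: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Assign a chromatin state per site.

    With planted effects, a fraction ``frac_pos_in_enriched`` of the
    positive-class sites goes to the enriched state, and the non-positive
    rate is adjusted so the OVERALL in-state fraction equals
    ``background_in_enriched`` — making the planted log2 enrichment exactly
    log2(frac_pos_in_enriched / background_in_enriched) up to rounding.
    """
    n = len(classes)
    states = np.array(STATE_NAMES, dtype=object)
    others = [s for s in STATE_NAMES if s != config.enriched_state]
    assignment = rng.choice(np.array(others, dtype=object), size=n)

    pos_idx = np.flatnonzero(classes == "positive")
    rest_idx = np.flatnonzero(classes != "positive")
    if config.plant_effects and pos_idx.size:
        n_pos_in = int(round(config.frac_pos_in_enriched * pos_idx.size))
        target_total = int(round(config.background_in_enriched * n))
        n_rest_in = max(target_total - n_pos_in, 0)
        n_rest_in = min(n_rest_in, rest_idx.size)
        chosen_pos = rng.choice(pos_idx, size=n_pos_in, replace=False)
        chosen_rest = rng.choice(rest_idx, size=n_rest_in, replace=False)
        assignment[chosen_pos] = config.enriched_state
        assignment[chosen_rest] = config.enriched_state
    else:
        # Null design: states independent of class, uniform over all states.
        assignment = rng.choice(states, size=n)
    return assignment


def generate_context_fixtures(
    matrix: MethylationMatrix, truth: TruthLabels, config: SynthConfig
) -> ContextFixtures:
    """Build segmentation, annotation, expression, homology and genotype fixtures.

    Every CpG falls in exactly one segmentation interval. With planted
    effects, positive-class sites are enriched in ``config.enriched_state``
    and get a gene TSS within 5 kb whose expression is scaled by
    ``config.expression_scale`` in every tissue.
    """
    config.validate()
    rng = config.rng(_STREAM_CONTEXT)
    classes = truth.site_class.to_numpy()
    site_state = _planted_state_assignment(classes, config, rng)

    # Segmentation: one interval per site (sites are >= _SITE_SPACING apart),
    # padded with quiescent filler between them so intervals tile each chrom.
    half = _SITE_SPACING // 4
    rows = []
    order = np.lexsort((matrix.pos, matrix.chrom.astype(str)))
    prev_chrom, prev_end = None, 0
    for i in order:
        c, p = matrix.chrom[i], int(matrix.pos[i])
        start, end = p - half, p + half
        if c != prev_chrom:
            prev_chrom, prev_end = c, 0
        if start > prev_end:
            rows.append((c, prev_end, start, "quiescent"))
        rows.append((c, start, end, site_state[i]))
        prev_end = end
    seg = ChromatinSegmentation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )

    # Gene annotation: one gene near every positive-class site (TSS within
    # 5 kb) plus background genes far from all sites.
    pos_idx = np.flatnonzero(classes == "positive")
    gene_rows = []
    planted_gene_ids = []
    for k, i in enumerate(pos_idx):
        gid = f"g{k:05d}"
        strand = "+" if k % 2 == 0 else "-"
        offset = int(rng.integers(200, 2000))
        gene_rows.append((gid, matrix.chrom[i], int(matrix.pos[i]) + offset, strand))
        planted_gene_ids.append(gid)
    n_background_genes = max(200, 2 * len(pos_idx))
    chrom_names = [f"chr{c + 1}" for c in range(_N_CHROMS)]
    far_base = int(matrix.pos.max()) + 1_000_000
    for k in range(n_background_genes):
        gid = f"bg{k:05d}"
        gene_rows.append(
            (gid, chrom_names[k % _N_CHROMS], far_base + 20_000 * (k // _N_CHROMS),
             "+" if k % 2 == 0 else "-")
        )
    ann = GeneAnnotation(
        pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss_pos", "strand"])
    )

    # Homolog map: every gene maps to exactly one expression-namespace id.
    all_genes = ann.genes["gene_id"].tolist()
    homolog_map = pd.DataFrame(
        {"gene_id": all_genes, "homolog_id": [f"XL-{g}" for g in all_genes]}
    )

    # Expression: per-gene base level x per-tissue multiplier, positive noise;
    # planted (positive-proximal) genes scaled down in every tissue.
    tissues = [f"tissue{j + 1}" for j in range(config.n_tissues)]
    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(all_genes))
    tissue_mult = rng.uniform(0.5, 1.5, size=config.n_tissues)
    noise = rng.lognormal(mean=0.0, sigma=0.1, size=(len(all_genes), config.n_tissues))
    expr_vals = base[:, None] * tissue_mult[None, :] * noise
    planted_homologs = []
    if config.plant_effects:
        planted_mask = np.isin(all_genes, planted_gene_ids)
        expr_vals[planted_mask, :] *= config.expression_scale
        planted_homologs = [f"XL-{g}" for g in planted_gene_ids]
    expression = pd.DataFrame(
        expr_vals, index=pd.Index([f"XL-{g}" for g in all_genes], name="gene_id"),
        columns=tissues,
    )

    genotypes = GenotypeMatrix(
        calls=truth.genotype.copy(), callable_sites=config.callable_sites
    ) if len(truth.genotype) else GenotypeMatrix(
        calls=pd.DataFrame(columns=matrix.samples), callable_sites=config.callable_sites
    )

    return ContextFixtures(
        segmentation=seg,
        annotation=ann,
        expression=expression,
        homolog_map=homolog_map,
        genotypes=genotypes,
        site_state=pd.Series(site_state, index=matrix.site_ids, name="state"),
        planted_genes=planted_homologs,
    )


def write_fixtures(
    outdir: str | Path,
    samples: pd.DataFrame,
    matrix: MethylationMatrix,
    truth: TruthLabels,
    context: ContextFixtures | None = None,
) -> dict[str, Path]:
    """Serialize a generated cohort to the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.csv",
        "beta": outdir / "methylation.tsv",
        "coverage": outdir / "coverage.tsv",
        "truth": outdir / "truth_labels.tsv",
    }
    write_sample_table(samples, paths["samples"])
    write_methylation_matrix(matrix, paths["beta"], paths["coverage"])
    truth_df = pd.DataFrame(
        {"site_class": truth.site_class, "true_slope": truth.true_slope}
    )
    truth_df.to_csv(paths["truth"], sep="\t")
    if context is not None:
        paths.update(
            {
                "segmentation": outdir / "segmentation.bed",
                "annotation": outdir / "genes.bed",
                "expression": outdir / "expression.tsv",
                "homologs": outdir / "homolog_map.tsv",
                "genotypes": outdir / "genotypes.tsv",
            }
        )
        write_segmentation_bed(context.segmentation, paths["segmentation"])
        write_gene_annotation_bed(context.annotation, paths["annotation"])
        context.expression.to_csv(paths["expression"], sep="\t")
        context.homolog_map.to_csv(paths["homologs"], sep="\t", header=False, index=False)
        write_genotype_matrix(context.genotypes, paths["genotypes"])
    return paths
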