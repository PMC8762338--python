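"""Synthetic cohorts with known immune-infiltration ground truth.

The generator plants three latent infiltration levels (low / mid / high)
and makes every downstream observable depend on them the way an immunically
stratified breast-cancer cohort would:

* marker-set genes shift upward with the level (the clustering signal),
  with the regulatory-T-cell set attenuated so the CD8/Treg balance also
  rises with infiltration;
* survival hazard decreases with the level (hot tumors do better);
* mutation burden (TMB) increases and recurrent copy-number burden (SCNA)
  decreases with the level;
* three planted mutation genes echo the classic patterns — one increasing
  with infiltration (TP53-like), one peaking in the middle (PIK3CA-like),
  one decreasing (GATA3-like) — over a bed of flat-rate genes;
* receptor composition skews triple-negative and HER2+ toward the high
  level and hormone-receptor-positive toward the low level;
* a single-cell variant plants the same latent levels on four immune
  pathways plus an HLA-like gene block ordered high > mid > low, with
  Bernoulli dropout.

Everything is reproducible from the config seed, and every written file
carries the config hash in a header comment.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, write_expression
from .genomic_scores import CopyNumberProfile, MutationCatalog, write_cnv, write_maf
from .signatures import GeneSet, GeneSetCollection, write_gmt

logger = logging.getLogger(__name__)

LEVELS = ("low", "mid", "high")

#: The 28 immune-cell-type signature names used for bulk subtyping.
IMMUNE_CELL_TYPES = (
    "Activated CD8 T cells", "Regulatory T cells", "Activated CD4 T cells",
    "Activated B cells", "Activated dendritic cells", "CD56bright NK cells",
    "CD56dim NK cells", "Central memory CD4 T cells",
    "Central memory CD8 T cells", "Effector memory CD4 T cells",
    "Effector memory CD8 T cells", "Eosinophils", "Gamma delta T cells",
    "Immature B cells", "Immature dendritic cells", "MDSC", "Macrophages",
    "Mast cells", "Memory B cells", "Monocytes", "NK cells",
    "Natural killer T cells", "Neutrophils", "Plasmacytoid dendritic cells",
    "T follicular helper cells", "Type 1 T helper cells",
    "Type 17 T helper cells", "Type 2 T helper cells",
)

#: The four immune pathways scored in single-cell mode.
SC_PATHWAYS = (
    "Antigen processing and presentation",
    "PD-L1 expression and PD-1 checkpoint",
    "JAK-STAT signaling",
    "Apoptosis",
)

RECEPTOR_CATEGORIES = ("TNBC", "HER2+", "HR+")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort (all rates per latent level,
    ordered low / mid / high)."""

    seed: int
    n_samples: int = 300
    n_cells: int = 300
    n_subtypes: int = 3
    subtype_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    n_genes: int = 2000
    n_marker_sets: int = 28
    genes_per_set: int = 10
    #: between-level mean shift of marker genes, in within-level SD units
    marker_shift: float = 2.0
    noise_sd: float = 1.0
    baseline_log2: float = 5.0
    #: shift attenuation for the regulatory-T-cell set, so the CD8/Treg
    #: log-ratio still rises with infiltration
    treg_shift_fraction: float = 0.5
    survival_baseline_hazard: float = 0.02
    hazard_multipliers: tuple[float, ...] = (1.0, 0.7, 0.45)
    censoring_rate: float = 0.3
    tmb_rates: tuple[float, ...] = (20.0, 35.0, 60.0)
    scna_rates: tuple[float, ...] = (0.5, 0.35, 0.2)
    n_regions: int = 80
    n_recurrent_regions: int = 60
    mutation_gene_rates: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        # planted patterns: increasing / middle-peaked / decreasing, with
        # per-level rates echoing commonly reported breast-cancer values
        "TP53L": (0.242, 0.257, 0.457),
        "PIK3CAL": (0.281, 0.413, 0.282),
        "GATA3L": (0.131, 0.108, 0.054),
        **{f"MUTBG{i:02d}": (0.10, 0.10, 0.10) for i in range(1, 18)},
    })
    silent_fraction: float = 0.3
    grade_g3_probs: tuple[float, ...] = (0.416, 0.486, 0.726)
    late_stage_probs: tuple[float, ...] = (0.055, 0.092, 0.123)
    receptor_probs: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        # per level (low, mid, high): P(TNBC), P(HER2+), P(HR+)
        "low": (0.054, 0.077, 0.869),
        "mid": (0.139, 0.124, 0.737),
        "high": (0.402, 0.206, 0.392),
    })
    til_means: tuple[float, ...] = (8.0, 18.0, 32.0)
    til_sd: float = 5.0
    methylation_means: tuple[float, ...] = (0.55, 0.60, 0.65)
    methylation_sd: float = 0.04
    n_hla_genes: int = 19
    #: genes per single-cell immune pathway (KEGG-scale sets are larger
    #: than cell-type marker sets)
    sc_pathway_genes: int = 40
    #: dropout probability at baseline expression; the per-entry probability
    #: halves for every log2 unit above baseline (expression-dependent
    #: dropout, as observed in scRNA-seq)
    dropout_rate: float = 0.3

    def validate(self) -> None:
        """Raise a single error listing every violated constraint."""
        problems = []
        k = self.n_subtypes
        if self.seed is None or int(self.seed) < 0:
            problems.append("seed must be a non-negative integer")
        if self.n_samples < 1:
            problems.append("n_samples must be >= 1")
        if self.n_cells < 1:
            problems.append("n_cells must be >= 1")
        if k != 3:
            problems.append("n_subtypes must be 3 (levels low/mid/high)")
        if len(self.subtype_proportions) != k or \
                not np.isclose(sum(self.subtype_proportions), 1.0) or \
                any(p <= 0 for p in self.subtype_proportions):
            problems.append("subtype_proportions must be positive and sum to 1")
        n_marker_genes = self.n_marker_sets * self.genes_per_set
        if self.n_marker_sets < 1 or self.n_marker_sets > len(IMMUNE_CELL_TYPES):
            problems.append(f"n_marker_sets must be in 1..{len(IMMUNE_CELL_TYPES)}")
        if self.genes_per_set < 2:
            problems.append("genes_per_set must be >= 2")
        if self.n_genes <= n_marker_genes:
            problems.append("n_genes must exceed total marker genes "
                            f"({n_marker_genes}) to leave background genes")
        if self.marker_shift < 0:
            problems.append("marker_shift must be >= 0")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if not (0 <= self.treg_shift_fraction <= 1):
            problems.append("treg_shift_fraction must lie in [0, 1]")
        if self.survival_baseline_hazard <= 0:
            problems.append("survival_baseline_hazard must be > 0")
        for name, rates, check in (
                ("hazard_multipliers", self.hazard_multipliers, lambda r: r > 0),
                ("tmb_rates", self.tmb_rates, lambda r: r >= 0),
                ("scna_rates", self.scna_rates, lambda r: 0 <= r <= 1),
                ("grade_g3_probs", self.grade_g3_probs, lambda r: 0 <= r <= 1),
                ("late_stage_probs", self.late_stage_probs, lambda r: 0 <= r <= 1),
                ("til_means", self.til_means, lambda r: r >= 0),
                ("methylation_means", self.methylation_means, lambda r: 0 <= r <= 1)):
            if len(rates) != k or not all(check(r) for r in rates):
                problems.append(f"{name} must be {k} valid per-level values")
        if not (0 <= self.censoring_rate < 1):
            problems.append("censoring_rate must lie in [0, 1)")
        if not (0 < self.n_recurrent_regions <= self.n_regions):
            problems.append("n_recurrent_regions must be in 1..n_regions")
        for gene, rates in self.mutation_gene_rates.items():
            if len(rates) != k or any(not (0 <= r <= 1) for r in rates):
                problems.append(f"mutation_gene_rates[{gene!r}] must be "
                                f"{k} probabilities")
        if not (0 <= self.silent_fraction <= 1):
            problems.append("silent_fraction must lie in [0, 1]")
        if set(self.receptor_probs) != set(LEVELS):
            problems.append("receptor_probs must have keys low/mid/high")
        else:
            for lev, probs in self.receptor_probs.items():
                if len(probs) != len(RECEPTOR_CATEGORIES) or \
                        not np.isclose(sum(probs), 1.0) or any(p < 0 for p in probs):
                    problems.append(f"receptor_probs[{lev!r}] must be "
                                    f"{len(RECEPTOR_CATEGORIES)} probabilities summing to 1")
        if self.n_hla_genes < 2:
            problems.append("n_hla_genes must be >= 2")
        if self.sc_pathway_genes < 2:
            problems.append("sc_pathway_genes must be >= 2")
        if self.n_genes <= 4 * self.sc_pathway_genes + self.n_hla_genes:
            problems.append("n_genes must exceed the single-cell planted genes "
                            f"({4 * self.sc_pathway_genes + self.n_hla_genes})")
        if not (0 <= self.dropout_rate <= 1):
            problems.append("dropout_rate must lie in [0, 1]")
        if problems:
            raise ValueError("invalid synthetic config:\n  - " + "\n  - ".join(problems))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:10]


@dataclass
class SyntheticTruth:
    """Ground truth: the latent infiltration level of every sample/cell,
    with the full planted configuration echoed."""

    levels: pd.Series  # sample_id -> "low" | "mid" | "high"
    config: SyntheticConfig

    def level_index(self) -> pd.Series:
        return self.levels.map({lev: i for i, lev in enumerate(LEVELS)})

    def samples_at(self, level: str) -> list[str]:
        return list(self.levels.index[self.levels == level])


@dataclass
class BulkDataset:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    mutations: MutationCatalog
    cnv: CopyNumberProfile
    marker_sets: GeneSetCollection
    truth: SyntheticTruth


@dataclass
class SingleCellDataset:
    expression: ExpressionMatrix
    pathway_sets: GeneSetCollection
    hla_genes: tuple[str, ...]
    cell_origins: pd.Series
    truth: SyntheticTruth


def _assign_levels(rng: np.random.Generator, n: int,
                   proportions: tuple[float, ...]) -> np.ndarray:
    """Deterministic largest-remainder level counts, randomly permuted."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    levels = np.repeat(np.arange(len(proportions)), counts)
    return rng.permutation(levels)


def _marker_collection(config: SyntheticConfig) -> tuple[GeneSetCollection, dict[str, float]]:
    sets = []
    multipliers = {}
    for i in range(config.n_marker_sets):
        name = IMMUNE_CELL_TYPES[i]
        genes = [f"MK{i:02d}G{j:02d}" for j in range(config.genes_per_set)]
        sets.append(GeneSet.from_genes(name, genes))
        multipliers[name] = (config.treg_shift_fraction
                             if name == "Regulatory T cells" else 1.0)
    return GeneSetCollection.from_sets(sets, source="synthetic"), multipliers


def _expression_from_levels(rng: np.random.Generator, config: SyntheticConfig,
                            level_idx: np.ndarray, sample_ids: list[str],
                            shifted_blocks: list[tuple[list[str], float]],
                            n_background: int) -> ExpressionMatrix:
    """Log2-scale matrix: baseline noise plus level-proportional block shifts."""
    gene_rows = []
    gene_names = []
    n = len(sample_ids)
    for genes, mult in shifted_blocks:
        shift = level_idx * config.marker_shift * config.noise_sd * mult
        for g in genes:
            gene_names.append(g)
            gene_rows.append(config.baseline_log2 + shift +
                             rng.normal(0.0, config.noise_sd, size=n))
    for m in range(n_background):
        gene_names.append(f"BG{m:04d}")
        gene_rows.append(config.baseline_log2 +
                         rng.normal(0.0, config.noise_sd, size=n))
    data = pd.DataFrame(np.vstack(gene_rows), index=gene_names, columns=sample_ids)
    return ExpressionMatrix(np.maximum(data, 0.0), scale="log2")


def generate_bulk_dataset(config: SyntheticConfig) -> BulkDataset:
    """Generate a bulk cohort: expression, clinical, mutation, copy-number
    tables and the planted marker sets, all keyed to the latent level."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    level_idx = _assign_levels(rng, n, config.subtype_proportions)
    levels = pd.Series([LEVELS[i] for i in level_idx], index=sample_ids,
                       name="level")

    marker_sets, multipliers = _marker_collection(config)
    blocks = [(list(gs.genes), multipliers[gs.name]) for gs in marker_sets]
    n_background = config.n_genes - sum(len(g) for g, _ in blocks)
    expression = _expression_from_levels(rng, config, level_idx, sample_ids,
                                         blocks, n_background)

    # survival: exponential event time racing an exponential censor time
    hazards = config.survival_baseline_hazard * \
        np.asarray(config.hazard_multipliers)[level_idx]
    event_time = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        c = config.censoring_rate
        censor_time = rng.exponential((1 - c) / (hazards * c))
        time = np.minimum(event_time, censor_time)
        event = event_time <= censor_time
    else:
        time = event_time
        event = np.ones(n, dtype=bool)

    grade = rng.random(n) < np.asarray(config.grade_g3_probs)[level_idx]
    stage = rng.random(n) < np.asarray(config.late_stage_probs)[level_idx]
    receptor = np.empty(n, dtype=object)
    for i, lev in enumerate(levels):
        receptor[i] = rng.choice(RECEPTOR_CATEGORIES,
                                 p=config.receptor_probs[lev])
    til = np.clip(rng.normal(np.asarray(config.til_means)[level_idx],
                             config.til_sd), 0.0, 100.0)
    methylation = np.clip(
        rng.normal(np.asarray(config.methylation_means)[level_idx],
                   config.methylation_sd), 0.0, 1.0)

    # mutation catalog: planted per-level driver genes plus Poisson filler
    driver_genes = list(config.mutation_gene_rates)
    records = []
    filler_counts = rng.poisson(np.asarray(config.tmb_rates)[level_idx])
    for i, sid in enumerate(sample_ids):
        li = level_idx[i]
        for gene in driver_genes:
            if rng.random() < config.mutation_gene_rates[gene][li]:
                records.append((sid, gene, "Missense_Mutation",
                                f"p.A{int(rng.integers(1, 500))}V"))
        for _ in range(int(filler_counts[i])):
            gene = f"PASS{int(rng.integers(0, 200)):03d}"
            vclass = ("Silent" if rng.random() < config.silent_fraction
                      else "Missense_Mutation")
            records.append((sid, gene, vclass, ""))
    mutations = MutationCatalog(
        records=pd.DataFrame(records, columns=["sample_id", "gene",
                                               "variant_class", "protein_change"]),
        samples=tuple(sample_ids))
    neoantigen = rng.poisson(np.maximum(filler_counts / 10.0, 0.1))

    # copy-number calls over flagged recurrent regions
    regions = [f"R{r:03d}" for r in range(config.n_regions)]
    recurrent = pd.Series([r < config.n_recurrent_regions
                           for r in range(config.n_regions)], index=regions)
    event_prob = np.where(
        recurrent.to_numpy()[:, None],
        np.asarray(config.scna_rates)[level_idx][None, :], 0.05)
    has_event = rng.random((config.n_regions, n)) < event_prob
    sign = rng.choice([-1, 1], size=(config.n_regions, n))
    magnitude = rng.choice([1, 2], size=(config.n_regions, n), p=[0.7, 0.3])
    calls = pd.DataFrame(np.where(has_event, sign * magnitude, 0),
                         index=regions, columns=sample_ids)
    cnv = CopyNumberProfile(calls=calls, recurrent=recurrent)

    clinical = pd.DataFrame({
        "time": time, "event": event.astype(int),
        "grade": np.where(grade, "G3", "G1-2"),
        "stage": np.where(stage, "III-IV", "I-II"),
        "receptor_status": receptor,
        "til_percent": til,
        "neoantigen_load": neoantigen,
        "methylation_level": methylation,
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth = SyntheticTruth(levels=levels, config=config)
    return BulkDataset(expression=expression, clinical=clinical,
                       mutations=mutations, cnv=cnv, marker_sets=marker_sets,
                       truth=truth)


def generate_single_cell_dataset(config: SyntheticConfig) -> SingleCellDataset:
    """Generate tumor cells with the latent levels planted on four immune
    pathways and an HLA-like block, plus Bernoulli dropout."""
    config.validate()
    rng = np.random.default_rng(config.seed + 10_007)
    n = config.n_cells
    cell_ids = [f"C{i:04d}" for i in range(n)]
    level_idx = _assign_levels(rng, n, config.subtype_proportions)
    levels = pd.Series([LEVELS[i] for i in level_idx], index=cell_ids,
                       name="level")

    pathway_sets = []
    blocks = []
    for i, name in enumerate(SC_PATHWAYS):
        genes = [f"PW{i}G{j:02d}" for j in range(config.sc_pathway_genes)]
        pathway_sets.append(GeneSet.from_genes(name, genes))
        blocks.append((genes, 1.0))
    hla_genes = tuple(f"HLAS{j:02d}" for j in range(config.n_hla_genes))
    blocks.append((list(hla_genes), 1.0))
    collection = GeneSetCollection.from_sets(pathway_sets, source="synthetic")
    n_planted = sum(len(g) for g, _ in blocks)
    n_background = config.n_genes - n_planted
    expression = _expression_from_levels(rng, config, level_idx, cell_ids,
                                         blocks, n_background)
    if config.dropout_rate > 0:
        values = expression.data.to_numpy()
        # dropout probability halves per log2 unit above baseline: lowly
        # expressed transcripts are the ones the library misses
        p_drop = np.minimum(1.0, config.dropout_rate *
                            np.exp2(-(values - config.baseline_log2)))
        mask = rng.random(values.shape) < p_drop
        expression = ExpressionMatrix(
            pd.DataFrame(np.where(mask, 0.0, values),
                         index=expression.genes, columns=expression.samples),
            scale="log2")

    origins = np.empty(n, dtype=object)
    origin_probs = {  # per level: P(TNBC), P(HER2+), P(ER+) of the cell's tumor
        "low": (0.15, 0.55, 0.30),
        "mid": (0.25, 0.30, 0.45),
        "high": (0.35, 0.45, 0.20),
    }
    categories = ("TNBC", "HER2+", "ER+")
    for i, lev in enumerate(levels):
        origins[i] = rng.choice(categories, p=origin_probs[lev])
    cell_origins = pd.Series(origins, index=cell_ids, name="origin")

    truth = SyntheticTruth(levels=levels, config=config)
    return SingleCellDataset(expression=expression, pathway_sets=collection,
                             hla_genes=hla_genes, cell_origins=cell_origins,
                             truth=truth)


def write_bulk_dataset(dataset: BulkDataset, out_dir) -> dict[str, Path]:
    """Write the bulk bundle as plain-text files the package's own readers
    accept unchanged. Returns the mapping of artifact name to path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.truth.config
    tag = f"synthetic config_hash={cfg.hash()} seed={cfg.seed}"
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.maf.tsv",
        "cnv": out / "cnv.tsv",
        "markers": out / "markers.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression(dataset.expression, paths["expression"], header_comment=tag)
    with open(paths["clinical"], "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n")
        dataset.clinical.to_csv(fh, sep="\t")
    write_maf(dataset.mutations, paths["mutations"], header_comment=tag)
    write_cnv(dataset.cnv, paths["cnv"], header_comment=tag)
    write_gmt(dataset.marker_sets, paths["markers"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write(f"# {tag}\n")
        dataset.truth.levels.to_frame().to_csv(fh, sep="\t")
    return paths
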