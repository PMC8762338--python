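"""End-to-end orchestration: score -> subtype -> characterize -> report.

Each characterization stage runs only when its input is available and
failures in one stage do not abort the independent ones; every table is
written deterministically (fixed float formatting, stable ordering) so a
rerun with the same config and seed is byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, genomic_scores, stats, subtyping
from .containers import read_expression
from .signatures import GeneSet, read_gmt

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Paths and analysis parameters for one pipeline run."""

    expression: str
    genesets: str
    out_dir: str
    clinical: str | None = None
    mutations: str | None = None
    cnv: str | None = None
    pathways: str | None = None
    features: str | None = None
    expression_scale: str = "log2"
    alpha: float = 0.25
    normalize: bool = False
    k: int = 3
    distance: str = "euclidean"
    linkage: str = "ward"
    standardize: bool = True
    deg_fdr: float = 0.05
    fc_threshold: float = 1.5
    pathway_fdr: float = 0.05
    mutation_fdr: float = 0.15
    min_mutated: int = 10
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not Path(self.expression).exists():
            problems.append(f"expression file not found: {self.expression}")
        if not Path(self.genesets).exists():
            problems.append(f"gene-set file not found: {self.genesets}")
        for name in ("clinical", "mutations", "cnv", "pathways", "features"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                problems.append(f"{name} file not found: {value}")
        for name, lo, hi in (("deg_fdr", 0, 1), ("pathway_fdr", 0, 1),
                             ("mutation_fdr", 0, 1)):
            v = getattr(self, name)
            if not (lo < v < hi):
                problems.append(f"{name} must lie in ({lo}, {hi})")
        if self.fc_threshold <= 1:
            problems.append("fc_threshold must exceed 1")
        if self.k < 2:
            problems.append("k must be >= 2")
        if problems:
            raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class PipelineReport:
    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return path


def _ordered_pairs(labels: tuple[str, ...]):
    """(higher, lower) label pairs: the one-tailed contrast orientation is
    always 'the higher-infiltration subtype has greater scores'."""
    return [(labels[i], labels[j]) for i in range(len(labels))
            for j in range(i + 1, len(labels))]


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage the inputs permit; see the run log for choices made."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out)
    log = report.log_lines.append

    def stage(name: str):
        def wrap(fn):
            try:
                fn()
                log(f"[ok] {name}")
            except Exception as exc:  # keep independent stages running
                report.errors[name] = str(exc)
                log(f"[failed] {name}: {exc}")
        return wrap

    matrix = read_expression(config.expression, scale=config.expression_scale)
    collection = read_gmt(config.genesets)
    log(f"inputs: {matrix.n_genes} genes x {matrix.n_samples} samples, "
        f"{len(collection)} gene sets")

    scores = enrichment.ssgsea_matrix(matrix, collection, alpha=config.alpha,
                                      normalize=config.normalize)
    report.tables["signature_scores"] = _write(scores.scores,
                                               out / "signature_scores.tsv")
    log(f"ssGSEA: alpha={config.alpha}, normalize={config.normalize}, "
        f"{len(scores.set_ids)} sets retained")

    assignment = subtyping.subtype_samples(
        scores, k=config.k, distance=config.distance, linkage=config.linkage,
        standardize=config.standardize)
    labels_seq = subtyping.ordered_labels(assignment.k)
    frame = assignment.to_frame()
    frame["mean_score"] = scores.sample_means().loc[frame["sample_id"]].to_numpy()
    report.tables["assignments"] = _write(frame.set_index("sample_id"),
                                          out / "assignments.tsv")
    log(f"subtyping: {config.linkage}/{config.distance}, k={config.k}, "
        "cluster means " +
        ", ".join(f"{l}={assignment.cluster_means[l]:.4g}" for l in labels_seq))

    # immune infiltration proxy: ssGSEA over the pooled marker genes
    pooled = []
    for gs in collection:
        pooled.extend(gs.genes)
    immune_set = GeneSet.from_genes("pooled_immune", pooled)
    immune = enrichment.immune_score(matrix, immune_set, alpha=config.alpha)
    report.tables["immune_scores"] = _write(immune.to_frame(),
                                            out / "immune_scores.tsv")
    log("immune score: ssGSEA infiltration proxy over the pooled marker genes")

    @stage("signature_contrasts")
    def _():
        rows = []
        for set_id in scores.set_ids:
            for hi, lo in _ordered_pairs(labels_seq):
                x = scores.scores.loc[set_id, assignment.samples_with(hi)]
                y = scores.scores.loc[set_id, assignment.samples_with(lo)]
                res = stats.mann_whitney(x, y, alternative="greater")
                rows.append({"signature": set_id, "contrast": f"{hi}>{lo}",
                             "statistic": res.statistic, "p": res.p_value,
                             "method": res.method})
        table = pd.DataFrame(rows).set_index("signature")
        table["fdr"] = stats.bh_fdr(table["p"].to_numpy())
        report.tables["signature_contrasts"] = _write(
            table, out / "signature_contrasts.tsv")
        log("signature contrasts: one-tailed Mann-Whitney, orientation "
            "higher-subtype > lower-subtype")

    clinical = None
    if config.clinical:
        clinical = pd.read_csv(config.clinical, sep="\t", index_col=0,
                               comment="#")
        clinical.index = clinical.index.astype(str)

    if clinical is not None and {"time", "event"} <= set(clinical.columns):
        @stage("survival")
        def _():
            shared = [s for s in assignment.sample_ids if s in clinical.index]
            groups = {lab: clinical.loc[[s for s in assignment.samples_with(lab)
                                         if s in shared], ["time", "event"]]
                      for lab in labels_seq}
            rows = []
            overall = stats.logrank_test(list(groups.values()))
            rows.append({"contrast": "all", "statistic": overall.statistic,
                         "p": overall.p_value})
            for hi, lo in _ordered_pairs(labels_seq):
                res = stats.logrank_test([groups[hi], groups[lo]])
                rows.append({"contrast": f"{hi} vs {lo}",
                             "statistic": res.statistic, "p": res.p_value})
            report.tables["survival_logrank"] = _write(
                pd.DataFrame(rows).set_index("contrast"),
                out / "survival_logrank.tsv")
            curves = []
            for lab in labels_seq:
                km = stats.km_estimate(groups[lab])
                for t, s, r in zip(km.event_times, km.survival, km.at_risk):
                    curves.append({"label": lab, "time": t, "survival": s,
                                   "at_risk": r})
            report.tables["km_curves"] = _write(
                pd.DataFrame(curves).set_index("label"), out / "km_curves.tsv")
            log("survival: Kaplan-Meier + log-rank, overall and pairwise")

    if clinical is not None:
        for column in ("grade", "stage", "receptor_status"):
            if column not in clinical.columns:
                continue

            @stage(f"composition_{column}")
            def _(column=column):
                props, res = differential.composition_test(
                    assignment, clinical[column], seed=config.seed)
                props = props.copy()
                props["p"] = res.p_value
                props["method"] = res.method
                report.tables[f"composition_{column}"] = _write(
                    props, out / f"composition_{column}.tsv")
                log(f"composition ({column}): {res.method}")

        for column in ("til_percent", "neoantigen_load", "methylation_level"):
            if column not in clinical.columns:
                continue

            @stage(f"covariate_{column}")
            def _(column=column):
                rows = []
                for hi, lo in _ordered_pairs(labels_seq):
                    x = clinical.loc[[s for s in assignment.samples_with(hi)
                                      if s in clinical.index], column].dropna()
                    y = clinical.loc[[s for s in assignment.samples_with(lo)
                                      if s in clinical.index], column].dropna()
                    res = stats.mann_whitney(x, y, alternative="greater")
                    rows.append({"contrast": f"{hi}>{lo}",
                                 "statistic": res.statistic, "p": res.p_value})
                report.tables[f"covariate_{column}"] = _write(
                    pd.DataFrame(rows).set_index("contrast"),
                    out / f"covariate_{column}.tsv")
                log(f"covariate ({column}): one-tailed Mann-Whitney, "
                    "higher-subtype > lower-subtype")

    catalog = None
    if config.mutations:
        catalog = genomic_scores.read_maf(config.mutations)

        @stage("tmb")
        def _():
            burdens = genomic_scores.tmb_all(catalog)
            shared = [s for s in assignment.sample_ids if s in burdens.index]
            rows = []
            for hi, lo in _ordered_pairs(labels_seq):
                x = burdens.loc[[s for s in assignment.samples_with(hi)
                                 if s in shared]]
                y = burdens.loc[[s for s in assignment.samples_with(lo)
                                 if s in shared]]
                res = stats.mann_whitney(x, y, alternative="greater")
                rows.append({"contrast": f"{hi}>{lo}",
                             "statistic": res.statistic, "p": res.p_value})
            report.tables["tmb"] = _write(burdens.to_frame(), out / "tmb.tsv")
            report.tables["tmb_tests"] = _write(
                pd.DataFrame(rows).set_index("contrast"), out / "tmb_tests.tsv")
            log("TMB: total mutation count; one-tailed Mann-Whitney ordering tests")

        @stage("mutation_screen")
        def _():
            screen = genomic_scores.genewise_mutation_screen(
                catalog, assignment, min_mutated=config.min_mutated,
                fdr_threshold=config.mutation_fdr, seed=config.seed)
            report.tables["mutation_screen"] = _write(
                screen, out / "mutation_screen.tsv")
            log(f"mutation screen: Fisher exact per gene, min_mutated="
                f"{config.min_mutated}, FDR<{config.mutation_fdr}")

    profile = None
    if config.cnv:
        profile = genomic_scores.read_cnv(config.cnv)

        @stage("scna")
        def _():
            burdens = genomic_scores.scna_scores_all(profile, mode="abs_sum")
            shared = [s for s in assignment.sample_ids if s in burdens.index]
            rows = []
            # SCNA burden is expected HIGHER in the lower-infiltration subtype
            for hi, lo in _ordered_pairs(labels_seq):
                x = burdens.loc[[s for s in assignment.samples_with(lo)
                                 if s in shared]]
                y = burdens.loc[[s for s in assignment.samples_with(hi)
                                 if s in shared]]
                res = stats.mann_whitney(x, y, alternative="greater")
                rows.append({"contrast": f"{lo}>{hi}",
                             "statistic": res.statistic, "p": res.p_value})
            report.tables["scna"] = _write(burdens.to_frame(), out / "scna.tsv")
            report.tables["scna_tests"] = _write(
                pd.DataFrame(rows).set_index("contrast"), out / "scna_tests.tsv")
            log("SCNA: abs-sum over recurrent regions; one-tailed tests, "
                "orientation lower-subtype > higher-subtype")

    if catalog is not None and profile is not None:
        @stage("logistic")
        def _():
            burdens = genomic_scores.tmb_all(catalog)
            scna = genomic_scores.scna_scores_all(profile, mode="abs_sum")
            shared = [s for s in immune.index
                      if s in burdens.index and s in scna.index]
            labels, dropped = stats.median_split(immune.loc[shared])
            fit = stats.logistic_standardized(
                labels.to_numpy(),
                pd.DataFrame({"tmb": burdens.loc[labels.index],
                              "scna": scna.loc[labels.index]}))
            table = pd.DataFrame({
                "coefficient": fit.coefficients,
                "standardized_beta": fit.standardized_betas,
                "p": fit.p_values,
            }, index=pd.Index(fit.predictor_names, name="predictor"))
            table["converged"] = fit.converged
            report.tables["logistic"] = _write(table, out / "logistic.tsv")
            log(f"logistic: high-vs-low immune score (median split, "
                f"{len(dropped)} at-median dropped) ~ TMB + SCNA; "
                "standardized betas = coef x predictor SD")

    if config.pathways:
        pathway_sets = read_gmt(config.pathways)

        @stage("deg_and_pathways")
        def _():
            hi_samples = assignment.samples_with(labels_seq[0])
            lo_samples = assignment.samples_with(labels_seq[-1])
            deg = differential.differential_genes(
                matrix, hi_samples, lo_samples,
                fc_threshold=config.fc_threshold, fdr_threshold=config.deg_fdr)
            report.tables["deg"] = _write(deg.table, out / "deg.tsv")
            up_high = deg.upregulated_in("a")
            ora = differential.ora_pathways(up_high, matrix.genes, pathway_sets,
                                            fdr_threshold=config.pathway_fdr)
            report.tables["pathways_up_high"] = _write(
                ora, out / "pathways_up_high.tsv")
            pw_scores = enrichment.ssgsea_matrix(matrix, pathway_sets,
                                                 alpha=config.alpha)
            corr = differential.pathway_immune_correlation(pw_scores, immune)
            report.tables["pathway_immune_correlation"] = _write(
                corr, out / "pathway_immune_correlation.tsv")
            log(f"DEG {labels_seq[0]} vs {labels_seq[-1]}: two-tailed t, "
                f"FDR<{config.deg_fdr}, FC>{config.fc_threshold}; "
                "ORA hypergeometric; Spearman pathway-immune correlation")

    if config.features:
        @stage("one_vs_rest_features")
        def _():
            feats = pd.read_csv(config.features, sep="\t", index_col=0,
                                comment="#")
            assigned = differential.one_vs_rest_features(
                feats, assignment, fdr_threshold=config.deg_fdr)
            rows = [{"subtype": lab, "feature": f}
                    for lab in labels_seq for f in assigned[lab]]
            table = pd.DataFrame(rows, columns=["subtype", "feature"])
            report.tables["one_vs_rest_features"] = _write(
                table.set_index("subtype"), out / "one_vs_rest_features.tsv")
            log("one-vs-rest features: higher in one subtype than BOTH others, "
                f"pairwise two-tailed t, family-wide FDR<{config.deg_fdr}")

    with open(out / "config_echo.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(report.log_lines) + "\n")
    return report
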