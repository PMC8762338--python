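"""Per-sample mutation and copy-number burden, and subtype mutation contrasts.

Tumor mutation burden (TMB) is the total count of somatic mutation records
for a sample (optionally restricted to nonsynonymous classes). The SCNA
score sums a sample's recurrent somatic copy-number alterations — either
the summed absolute GISTIC-style call magnitude (default) or the count of
altered recurrent regions. Recurrence is an input flag: regions arrive
pre-marked, since recurrence definitions are cohort-level decisions made
upstream of this package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .containers import normalize_symbol
from .stats import bh_fdr, fisher_exact
from .subtyping import SubtypeAssignment, ordered_labels

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Variant_Classification values counted when nonsynonymous_only is set.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

MAF_REQUIRED = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


@dataclass
class MutationCatalog:
    """Somatic mutation records plus the explicit sample universe.

    ``records`` has one row per mutation event with columns ``sample_id``,
    ``gene``, ``variant_class`` and optional ``protein_change``. ``samples``
    lists every profiled sample, so a sample with zero records is
    distinguishable from a sample that was never sequenced.
    """

    records: pd.DataFrame
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "variant_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation records missing columns: {sorted(missing)}")
        if "protein_change" not in self.records.columns:
            self.records = self.records.assign(protein_change="")
        self.records = self.records.copy()
        self.records["sample_id"] = self.records["sample_id"].astype(str)
        self.records["gene"] = [normalize_symbol(g) for g in self.records["gene"]]
        if (self.records["sample_id"].str.len() == 0).any():
            raise ValueError("sample identifiers must be non-empty")
        self.samples = tuple(str(s) for s in self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        unknown = set(self.records["sample_id"]) - set(self.samples)
        if unknown:
            raise ValueError(f"records reference samples outside the universe: "
                             f"{sorted(unknown)[:5]}")

    def has_sample(self, sample_id: str) -> bool:
        return str(sample_id) in self.samples

    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())


def read_maf(path: PathLike, all_samples: Iterable[str] | None = None) -> MutationCatalog:
    """Read a MAF-like TSV (only the three standard columns are required).

    Rows whose ``Hugo_Symbol`` is empty or ``.`` register the sample in the
    universe without contributing a mutation (the explicit zero-mutation
    convention). ``all_samples`` may extend the universe further.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing required columns: {missing}")
    df = df.rename(columns={"Tumor_Sample_Barcode": "sample_id",
                            "Hugo_Symbol": "gene",
                            "Variant_Classification": "variant_class"})
    if "Protein_Change" in df.columns:
        df = df.rename(columns={"Protein_Change": "protein_change"})
    placeholder = df["gene"].isna() | df["gene"].str.strip().isin(["", "."])
    universe = list(dict.fromkeys(df["sample_id"].astype(str)))
    if all_samples is not None:
        for s in all_samples:
            if str(s) not in universe:
                universe.append(str(s))
    records = df.loc[~placeholder,
                     [c for c in ("sample_id", "gene", "variant_class",
                                  "protein_change") if c in df.columns]]
    return MutationCatalog(records=records.reset_index(drop=True),
                           samples=tuple(universe))


def write_maf(catalog: MutationCatalog, path: PathLike,
              header_comment: str | None = None) -> None:
    """Write a MAF-like TSV; zero-record samples get a placeholder row."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\t"
                 "Protein_Change\n")
        with_records = set(catalog.records["sample_id"])
        for _, row in catalog.records.iterrows():
            fh.write(f"{row['sample_id']}\t{row['gene']}\t{row['variant_class']}\t"
                     f"{row.get('protein_change', '')}\n")
        for s in catalog.samples:
            if s not in with_records:
                fh.write(f"{s}\t.\t.\t\n")


def tmb(catalog: MutationCatalog, sample_id: str,
        nonsynonymous_only: bool = False) -> int:
    """Tumor mutation burden: the sample's total somatic mutation count."""
    sample_id = str(sample_id)
    if not catalog.has_sample(sample_id):
        raise KeyError(f"sample {sample_id!r} not in the mutation catalog")
    sub = catalog.records[catalog.records["sample_id"] == sample_id]
    if nonsynonymous_only:
        sub = sub[sub["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    return int(len(sub))


def tmb_all(catalog: MutationCatalog, nonsynonymous_only: bool = False) -> pd.Series:
    """TMB for every sample in the catalog's universe."""
    recs = catalog.records
    if nonsynonymous_only:
        recs = recs[recs["variant_class"].isin(NONSYNONYMOUS_CLASSES)]
    counts = recs["sample_id"].value_counts()
    return pd.Series([int(counts.get(s, 0)) for s in catalog.samples],
                     index=list(catalog.samples), name="tmb")


@dataclass
class CopyNumberProfile:
    """Discretized copy-number calls (GISTIC-style, in {-2..2}) by region."""

    calls: pd.DataFrame  # region x sample, integer calls
    recurrent: pd.Series  # region -> bool

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(int)
        values = self.calls.to_numpy()
        if ((values < -2) | (values > 2)).any():
            raise ValueError("copy-number calls must lie in {-2,-1,0,1,2}")
        self.recurrent = self.recurrent.astype(bool).reindex(self.calls.index)
        if self.recurrent.isna().any():
            raise ValueError("recurrent flags must cover every region")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def regions(self) -> list[str]:
        return list(self.calls.index)


def read_cnv(path: PathLike) -> CopyNumberProfile:
    """Read a region-by-sample TSV of integer calls with a `recurrent` column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "recurrent" not in df.columns:
        raise ValueError("copy-number table must carry a 'recurrent' boolean column")
    rec = df["recurrent"].astype(bool)
    calls = df.drop(columns=["recurrent"])
    return CopyNumberProfile(calls=calls, recurrent=rec)


def write_cnv(profile: CopyNumberProfile, path: PathLike,
              header_comment: str | None = None) -> None:
    out = profile.calls.copy()
    out.insert(0, "recurrent", profile.recurrent.astype(bool))
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t")


def scna_score(profile: CopyNumberProfile, sample_id: str,
               mode: str = "abs_sum") -> float:
    """Recurrent SCNA burden of one sample.

    ``abs_sum`` sums |call| over recurrent regions (amplitude-weighted);
    ``event_count`` counts recurrent regions with a non-zero call.
    """
    if mode not in ("abs_sum", "event_count"):
        raise ValueError("mode must be 'abs_sum' or 'event_count'")
    sample_id = str(sample_id)
    if sample_id not in profile.calls.columns:
        raise KeyError(f"sample {sample_id!r} not in the copy-number profile")
    if not profile.recurrent.any():
        raise ValueError("no regions flagged recurrent")
    calls = profile.calls.loc[profile.recurrent.to_numpy(), sample_id].to_numpy()
    if mode == "abs_sum":
        return float(np.abs(calls).sum())
    return float((calls != 0).sum())


def scna_scores_all(profile: CopyNumberProfile, mode: str = "abs_sum") -> pd.Series:
    return pd.Series({s: scna_score(profile, s, mode=mode) for s in profile.samples},
                     name=f"scna_{mode}")


def _shared_subtype_samples(catalog: MutationCatalog,
                            assignment: SubtypeAssignment) -> dict[str, list[str]]:
    in_catalog = set(catalog.samples)
    out = {}
    for label in ordered_labels(assignment.k):
        members = [s for s in assignment.samples_with(label) if s in in_catalog]
        out[label] = members
    return out


def mutation_rate_table(catalog: MutationCatalog, assignment: SubtypeAssignment,
                        gene: str) -> tuple[pd.Series, pd.DataFrame]:
    """Per-subtype mutated fractions for one gene, plus the 2xk table.

    Returns ``(proportions, table)`` where the table rows are
    mutated / wild-type counts per subtype, ready for Fisher's exact test.
    A gene absent from the catalog yields all-zero proportions (valid,
    with a warning), not an error.
    """
    gene = normalize_symbol(gene)
    groups = _shared_subtype_samples(catalog, assignment)
    if any(len(m) == 0 for m in groups.values()):
        raise ValueError("every subtype needs >=1 sample with mutation data")
    carriers = set(catalog.records.loc[catalog.records["gene"] == gene, "sample_id"])
    if not carriers:
        logger.warning("gene %r has no mutation records in the catalog", gene)
    mutated = {lab: sum(1 for s in m if s in carriers) for lab, m in groups.items()}
    totals = {lab: len(m) for lab, m in groups.items()}
    props = pd.Series({lab: mutated[lab] / totals[lab] for lab in groups},
                      name=gene)
    table = pd.DataFrame(
        {lab: [mutated[lab], totals[lab] - mutated[lab]] for lab in groups},
        index=["mutated", "wild_type"])
    return props, table


def genewise_mutation_screen(catalog: MutationCatalog,
                             assignment: SubtypeAssignment,
                             min_mutated: int = 10,
                             fdr_threshold: float = 0.15,
                             seed: int = 0) -> pd.DataFrame:
    """Screen every gene for subtype-differential mutation frequency.

    Genes with at least ``min_mutated`` mutated samples are tested by
    Fisher's exact test on their mutated/wild-type-by-subtype table;
    Benjamini-Hochberg FDR is applied across the tested genes and rows
    under ``fdr_threshold`` are flagged.
    """
    groups = _shared_subtype_samples(catalog, assignment)
    if any(len(m) < 3 for m in groups.values()):
        raise ValueError("every subtype needs >=3 samples with mutation data")
    shared = set().union(*groups.values())
    recs = catalog.records[catalog.records["sample_id"].isin(shared)]
    carrier_counts = recs.groupby("gene")["sample_id"].nunique()
    genes = sorted(carrier_counts.index[carrier_counts >= min_mutated])
    if not genes:
        logger.warning("no gene reaches min_mutated=%d; empty screen", min_mutated)
        cols = [f"rate_{lab}" for lab in groups] + ["n_mutated", "p", "fdr",
                                                    "significant"]
        return pd.DataFrame(columns=["gene"] + cols).set_index("gene")
    rows = []
    for gene in genes:
        props, table = mutation_rate_table(catalog, assignment, gene)
        # a gene mutated in every shared sample has no contrast to test
        if (table.loc["wild_type"] == 0).all():
            p = 1.0
        else:
            p = fisher_exact(table.to_numpy(), seed=seed).p_value
        row = {f"rate_{lab}": props[lab] for lab in groups}
        row["n_mutated"] = int(table.loc["mutated"].sum())
        row["p"] = p
        rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out
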