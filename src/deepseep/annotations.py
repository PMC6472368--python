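"""Rule-based functional-potential calling from genome annotation hit tables.

Input is a flat table of similarity-search hits (one row per gene hit:
genome, gene, gene family, pathway label, e-value, percent identity,
coverage fraction), as produced by KEGG/CAZyme/peptidase/custom-database
searches of metagenome-assembled genomes.  Three interpretive layers are
implemented:

* per-database score filtering at the search tool's published cutoffs
  (inclusive comparisons: a hit exactly at the cutoff is retained);
* pathway presence calling: a pathway is called present in a genome when at
  least a minimum number of *distinct* gene families from that pathway
  survive filtering (multi-gene rules for glycolysis, beta-oxidation, the
  Wood-Ljungdahl pathway and the TCA cycle; single-marker rules otherwise);
* marker-gene censuses over unassembled reads, reported as relative
  frequencies (and optionally hits per million reads).

A Chao1 richness estimator for community count vectors is included for
amplicon-style diversity summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "genome_id", "gene_id", "family_id", "pathway_label",
    "evalue", "identity_pct", "coverage_frac", "bitscore", "database_tag",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DatabaseCutoff:
    """Score thresholds for one annotation database (None = field not tested)."""

    max_evalue: float
    min_identity_pct: float | None = None
    min_coverage_frac: float | None = None

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.min_identity_pct is not None and not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.min_coverage_frac is not None and not (0 < self.min_coverage_frac <= 1):
            raise ValueError("min_coverage_frac must be in (0, 1]")


#: Published per-database cutoffs: CAZyme search (coverage 0.40, e-value
#: 1e-18), peptidase and custom-database protein searches (e-value 1e-20,
#: identity 30%), read-level marker searches (e-value 1e-10, identity 70%).
DEFAULT_DATABASE_CUTOFFS: dict[str, DatabaseCutoff] = {
    "dbcan": DatabaseCutoff(max_evalue=1e-18, min_coverage_frac=0.40),
    "merops": DatabaseCutoff(max_evalue=1e-20, min_identity_pct=30.0),
    "custom": DatabaseCutoff(max_evalue=1e-20, min_identity_pct=30.0),
    "reads": DatabaseCutoff(max_evalue=1e-10, min_identity_pct=70.0),
}

#: Minimum distinct gene families for multi-gene pathway presence calls.
DEFAULT_PATHWAY_MIN_GENES: dict[str, int] = {
    "glycolysis_EMP": 5,
    "beta_oxidation": 3,
    "wood_ljungdahl": 4,
    "tca_cycle": 6,
}


@dataclass(frozen=True)
class RuleSet:
    """Per-database cutoffs plus per-pathway minimum distinct-gene counts."""

    database_cutoffs: Mapping[str, DatabaseCutoff] = field(
        default_factory=lambda: dict(DEFAULT_DATABASE_CUTOFFS))
    pathway_min_genes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_MIN_GENES))
    default_min_genes: int = 1

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.pathway_min_genes.values()) or self.default_min_genes < 1:
            raise ValueError("pathway minimum gene counts must be >= 1")

    def min_genes(self, pathway: str) -> int:
        return int(self.pathway_min_genes.get(pathway, self.default_min_genes))

    @classmethod
    def default(cls) -> "RuleSet":
        return cls()


def load_pathway_catalog(path: Union[str, Path, None] = None) -> dict[str, list[str]]:
    """Pathway -> gene-family list; defaults to the bundled KEGG-style catalog."""
    if path is None:
        with resources.as_file(resources.files("deepseep.data") / "pathway_families.tsv") as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {p: sorted(g["family_id"].unique()) for p, g in df.groupby("pathway", sort=True)}


def read_hits_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a hit table TSV, tolerant of missing optional columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"genome_id", "family_id", "evalue"} - set(df.columns)
    if missing:
        raise ValueError(f"hit table lacks required columns: {sorted(missing)}")
    return df


def filter_hits(hits: pd.DataFrame, ruleset: RuleSet, database_tag: str) -> pd.DataFrame:
    """Retain hits passing the (inclusive) cutoffs of ``database_tag``.

    A hit is retained iff ``evalue <= max_e`` and, where the database tests
    them, ``identity_pct >= min_id`` and ``coverage_frac >= min_cov``.
    Row order is preserved and no field is mutated.
    """
    try:
        cutoff = ruleset.database_cutoffs[database_tag]
    except KeyError:
        known = sorted(ruleset.database_cutoffs)
        raise KeyError(f"unknown database tag {database_tag!r}; known tags: {known}") from None
    if hits.empty:
        return hits.copy()
    mask = hits["evalue"] <= cutoff.max_evalue
    if cutoff.min_identity_pct is not None:
        if "identity_pct" not in hits.columns:
            raise ValueError(f"database {database_tag!r} tests identity_pct but column is absent")
        mask &= hits["identity_pct"] >= cutoff.min_identity_pct
    if cutoff.min_coverage_frac is not None:
        if "coverage_frac" not in hits.columns:
            raise ValueError(f"database {database_tag!r} tests coverage_frac but column is absent")
        mask &= hits["coverage_frac"] >= cutoff.min_coverage_frac
    return hits.loc[mask].copy()


def filter_hits_by_tag(hits: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Apply each hit's own ``database_tag`` rule; order-stable."""
    if hits.empty:
        return hits.copy()
    parts = [filter_hits(group, ruleset, tag) for tag, group in hits.groupby("database_tag", sort=False)]
    return pd.concat(parts).sort_index()


def profile_from_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Genome x pathway table of distinct retained gene-family counts."""
    if hits.empty:
        return pd.DataFrame(dtype=int)
    counts = (
        hits.groupby(["genome_id", "pathway_label"], sort=True)["family_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    counts.index.name = "genome_id"
    counts.columns.name = "pathway"
    return counts.astype(int)


@dataclass(frozen=True)
class PresenceMatrix:
    """Genome x pathway boolean presence with supporting distinct-gene counts."""

    presence: pd.DataFrame
    counts: pd.DataFrame
    thresholds: Mapping[str, int]
    unruled_pathways: tuple[str, ...] = ()


def call_pathways(profile: pd.DataFrame, ruleset: RuleSet | None = None) -> PresenceMatrix:
    """Apply minimum distinct-gene-count rules to a genome x pathway count table.

    A pathway with no explicit rule is called with the single-marker rule
    (>= 1 distinct family), flagged in ``unruled_pathways`` with a warning.
    """
    ruleset = ruleset or RuleSet.default()
    if profile.empty:
        empty = profile.astype(bool) if profile.size else pd.DataFrame(dtype=bool)
        return PresenceMatrix(empty, profile.copy(), {}, ())
    thresholds = {p: ruleset.min_genes(p) for p in profile.columns}
    unknown = tuple(p for p in profile.columns if p not in ruleset.pathway_min_genes)
    if unknown:
        warnings.warn(
            f"pathways without an explicit rule, called with >= {ruleset.default_min_genes}: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    presence = profile.ge(pd.Series(thresholds)).astype(bool)
    return PresenceMatrix(presence, profile.copy(), thresholds, unknown)


def marker_census(
    hits: pd.DataFrame,
    category_map: Mapping[str, str],
    total_reads: int | None = None,
) -> pd.DataFrame:
    """Relative-frequency census of marker-gene hits by category.

    ``category_map`` maps ``family_id`` -> category (e.g. hydrogenase
    subtype); hits with no category are counted under ``"unassigned"`` and
    excluded from the fraction denominator.  Fractions over categorized hits
    sum to 1.  With ``total_reads``, hits-per-million-reads is added.
    """
    if hits.empty:
        raise ValueError("no hits to census")
    categories = hits["family_id"].map(lambda f: category_map.get(f, UNASSIGNED))
    counts = categories.value_counts().sort_index()
    categorized = counts.drop(UNASSIGNED, errors="ignore")
    if categorized.sum() == 0:
        raise ValueError("zero categorized hits: fractions undefined")
    out = counts.rename_axis("category").to_frame("n_hits")
    out["fraction"] = categorized / categorized.sum()
    if total_reads is not None:
        if total_reads <= 0:
            raise ValueError("total_reads must be positive")
        out["hits_per_million_reads"] = out["n_hits"] * 1e6 / total_reads
    return out.reset_index()


def chao1(counts: Sequence[int] | np.ndarray | pd.Series, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from a vector of per-taxon counts.

    Classic form ``S_obs + F1^2 / (2 F2)`` (requires doubletons, F2 > 0);
    bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is always
    defined.  F1/F2 are the singleton/doubleton counts.  The estimate is
    always >= S_obs.
    """
    v = np.asarray(pd.Series(counts).to_numpy())
    if v.size and (v < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(v, np.round(v)):
        raise ValueError("counts must be integers")
    v = np.round(v).astype(np.int64)
    s_obs = int((v > 0).sum())
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        raise ValueError("no doubletons: classic Chao1 undefined, use bias_corrected=True")
    return s_obs + f1 * f1 / (2.0 * f2)
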