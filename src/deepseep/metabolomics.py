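"""Metabolite intensity normalization and replicate summaries.

LC-MS metabolite intensities vary with total organic content of the
extracted sediment, so intensities are expressed as fractional abundance
relative to all observed metabolites in the same sample (constant-sum
normalization) and visualized on a log10 scale.  The expected study design
is a compounds x samples matrix with a few sites and several technical
replicates per site (5 in the design this package mirrors); replicate
summaries report per-site means and coefficients of variation of the
fractional abundances.

Zeros are kept through normalization and only floored when taking logs
(default floor 1e-6 of total signal), so the log display convention never
feeds back into the fractions themselves.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def constant_sum_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its own total so columns sum to 1.

    Raises on negative intensities or an all-zero column (named in the
    error).  Idempotent: normalizing an already-normalized table is a no-op.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    totals = table.sum(axis=0)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValueError(f"all-zero sample column(s): {dead}")
    return table.div(totals, axis=1)


def log_fractional(table: pd.DataFrame, floor: float = 1e-6) -> pd.DataFrame:
    """log10 of fractional abundances, flooring entries at ``floor``.

    Input should be constant-sum normalized.  The floor used is recorded in
    ``result.attrs["floor"]``.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    out = np.log10(table.clip(lower=floor))
    out.attrs["floor"] = floor
    return out


def replicate_summary(
    fractions: pd.DataFrame,
    sample_sites: Mapping[str, str],
) -> pd.DataFrame:
    """Per-site mean and CV of fractional abundance for each compound.

    ``sample_sites`` maps sample column -> site id.  CV is the sample
    (n-1 denominator) standard deviation over the site's replicates divided
    by the mean; for a single-replicate site the CV column is NaN (flagged
    absent).  Returns a compounds-indexed frame with MultiIndex columns
    (site, {"mean", "cv"}).
    """
    missing = [c for c in fractions.columns if c not in sample_sites]
    if missing:
        raise ValueError(f"samples with no site assignment: {missing}")
    site_of = pd.Series({c: sample_sites[c] for c in fractions.columns})
    blocks = {}
    for site, cols in site_of.groupby(site_of).groups.items():
        block = fractions[list(cols)]
        mean = block.mean(axis=1)
        if block.shape[1] >= 2:
            sd = block.std(axis=1, ddof=1)
            cv = (sd / mean.where(mean != 0)).where(sd != 0, 0.0)
        else:
            cv = pd.Series(np.nan, index=fractions.index)
        blocks[(site, "mean")] = mean
        blocks[(site, "cv")] = cv
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["site", "stat"])
    return out.sort_index(axis=1)


def pathway_ordered_matrix(
    fractions: pd.DataFrame,
    pathway_map: Mapping[str, str],
    sample_sites: Mapping[str, str] | None = None,
    sample_replicates: Mapping[str, int] | None = None,
    dual_pathway: Sequence[str] = (),
    floor: float = 1e-6,
) -> pd.DataFrame:
    """Heatmap-ready long table grouped by pathway then compound.

    Compounds lacking a pathway label fall under ``"unassigned"``; compounds
    listed in ``dual_pathway`` (intermediates of more than one route) are
    flagged.  Row order is (pathway, compound) lexicographic and stable; the
    row multiset is exactly the input matrix reshaped.
    """
    long = fractions.rename_axis("compound").reset_index().melt(
        id_vars="compound", var_name="sample", value_name="fraction"
    )
    long["pathway"] = long["compound"].map(lambda c: pathway_map.get(c, "unassigned"))
    long["dual_pathway"] = long["compound"].isin(set(dual_pathway))
    long["log_fraction"] = np.log10(long["fraction"].clip(lower=floor))
    if sample_sites is not None:
        long["site"] = long["sample"].map(dict(sample_sites))
    if sample_replicates is not None:
        long["replicate"] = long["sample"].map(dict(sample_replicates))
    long = long.sort_values(["pathway", "compound", "sample"], kind="stable").reset_index(drop=True)
    cols = ["pathway", "compound"] + [c for c in ("site", "replicate") if c in long.columns] + [
        "sample", "fraction", "log_fraction", "dual_pathway"
    ]
    return long[cols]
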