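"""Seeded generators for every input the pipeline consumes, with ground truth.

These generators stand in for the field data a seep-sediment study would
collect — genome annotation hit tables, site gas profiles, metabolite
intensity matrices and amplicon count vectors — and return the planted
truth alongside each dataset so recovery can be checked exactly:

* genome hits: planted pathway gene families receive hits that pass their
  database cutoffs; spurious hits are drawn strictly outside the cutoffs
  (at least one order of magnitude past the e-value threshold) so score
  filtering separates them without ambiguity;
* gas profiles: biogenic sites are drawn inside the biogenic Bernard band
  (ratio > 1000, d13C < -60), thermogenic sites inside the thermogenic
  band, and "mixed" sites with deliberately conflicting evidence;
* metabolite matrices: log-normal intensities around planted per-site mean
  levels with a chosen technical coefficient of variation, replicated per
  the 3-sites x 5-technical-replicates design;
* community counts: multinomial samples from long-tailed (geometric or
  log-series) rank-abundance models with known true richness.

One global seed fans out to fixed, independent per-generator streams, so
adding a generator never perturbs the outputs of existing ones.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .annotations import (
    HIT_COLUMNS,
    RuleSet,
    load_pathway_catalog,
)

# Fixed stream keys: appending new generators never shifts existing streams.
_STREAMS = {"genome_hits": 1, "gas_profiles": 2, "metabolites": 3, "asv_counts": 4}

METABOLITE_PATHWAYS = (
    "carbohydrate_metabolism",
    "amino_acid_metabolism",
    "beta_oxidation",
    "benzoyl_coa_pathway",
    "fumarate_addition",
    "nucleotide_metabolism",
    "lipid_metabolism",
    "tca_cycle",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],)))


def gen_genome_hits(
    n_genomes: int,
    catalog: Mapping[str, Sequence[str]] | None = None,
    planted_sets: Mapping[str, Mapping[str, int]] | None = None,
    spurious_rate: float = 0.0,
    seed: int = 0,
    database_tag: str = "custom",
    ruleset: RuleSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate an annotation hit table with planted pathway gene sets.

    ``planted_sets`` maps genome -> {pathway: number of distinct families to
    plant}; if omitted, counts are drawn per genome/pathway to straddle the
    presence thresholds (absent, one-below, or at/above).  ``spurious_rate``
    is the per-genome, per-catalog-family probability of one sub-threshold
    decoy hit.  Returns ``(hits, truth)`` where truth records the planted
    family counts and the presence matrix they imply under the rule set.
    """
    if not 0.0 <= spurious_rate <= 1.0:
        raise ValueError(f"spurious_rate must be in [0, 1], got {spurious_rate}")
    catalog = catalog or load_pathway_catalog()
    ruleset = ruleset or RuleSet.default()
    rng = _rng(seed, "genome_hits")
    genomes = [f"genome_{i:03d}" for i in range(n_genomes)]

    if planted_sets is None:
        planted_sets = {}
        for g in genomes:
            per_pathway = {}
            for pathway, families in catalog.items():
                need = min(ruleset.min_genes(pathway), len(families))
                u = rng.random()
                if u < 0.35:
                    n = 0
                elif u < 0.55 and need > 1:
                    n = rng.integers(1, need)  # below threshold
                else:
                    n = rng.integers(need, len(families) + 1)  # at/above threshold
                if n:
                    per_pathway[pathway] = int(n)
            planted_sets[g] = per_pathway
    else:
        for g, per_pathway in planted_sets.items():
            for pathway, n in per_pathway.items():
                if pathway not in catalog:
                    raise ValueError(f"planted pathway {pathway!r} not in catalog")
                if n > len(catalog[pathway]):
                    raise ValueError(
                        f"cannot plant {n} families in {pathway!r} (catalog has {len(catalog[pathway])})"
                    )
        genomes = sorted(planted_sets)

    rows = []
    gene_serial = 0
    for g in genomes:
        for pathway in sorted(planted_sets.get(g, {})):
            n = planted_sets[g][pathway]
            families = list(catalog[pathway])[:n]
            for fam in families:
                gene_serial += 1
                rows.append(
                    dict(
                        genome_id=g,
                        gene_id=f"gene_{gene_serial:06d}",
                        family_id=fam,
                        pathway_label=pathway,
                        evalue=10.0 ** rng.uniform(-40, -25),
                        identity_pct=rng.uniform(40, 95),
                        coverage_frac=rng.uniform(0.5, 1.0),
                        bitscore=rng.uniform(100, 500),
                        database_tag=database_tag,
                        planted=True,
                    )
                )
        if spurious_rate > 0:
            for pathway in sorted(catalog):
                for fam in catalog[pathway]:
                    if rng.random() >= spurious_rate:
                        continue
                    gene_serial += 1
                    # fail the cutoffs decisively: e-value >= 10x the
                    # threshold, or identity below the 30% floor
                    if rng.random() < 0.5:
                        evalue, identity = 10.0 ** rng.uniform(-19, -10), rng.uniform(35, 90)
                    else:
                        evalue, identity = 10.0 ** rng.uniform(-40, -25), rng.uniform(5.0, 29.0)
                    rows.append(
                        dict(
                            genome_id=g,
                            gene_id=f"gene_{gene_serial:06d}",
                            family_id=fam,
                            pathway_label=pathway,
                            evalue=evalue,
                            identity_pct=identity,
                            coverage_frac=rng.uniform(0.5, 1.0),
                            bitscore=rng.uniform(20, 90),
                            database_tag=database_tag,
                            planted=False,
                        )
                    )
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS + ["planted"])

    planted_counts = pd.DataFrame(
        {g: {p: planted_sets.get(g, {}).get(p, 0) for p in sorted(catalog)} for g in genomes}
    ).T.rename_axis("genome_id")
    planted_counts.columns.name = "pathway"
    thresholds = {p: ruleset.min_genes(p) for p in planted_counts.columns}
    presence_truth = planted_counts.ge(pd.Series(thresholds)).astype(bool)
    truth = {
        "seed": int(seed),
        "planted_counts": planted_counts,
        "presence": presence_truth,
        "thresholds": thresholds,
    }
    return hits, truth


def gen_gas_profiles(
    n_sites: int,
    regimes: Union[str, Sequence[str]] = "biogenic",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate site gas-geochemistry tables from known origin regimes.

    ``regimes`` is a single regime name or one per site, each in
    {"biogenic", "thermogenic", "mixed"}.  Biogenic sites are constructed
    with Bernard ratio > 1000 and d13C < -60 permil; thermogenic sites with
    ratio < 100 and d13C > -50; mixed sites with conflicting evidence
    (biogenic ratio, thermogenic isotopes).  Returns ``(profiles, truth)``.
    """
    if isinstance(regimes, str):
        regimes = [regimes] * n_sites
    if len(regimes) != n_sites:
        raise ValueError(f"need {n_sites} regimes, got {len(regimes)}")
    allowed = {"biogenic", "thermogenic", "mixed"}
    bad = set(regimes) - allowed
    if bad:
        raise ValueError(f"unknown regimes {sorted(bad)}; allowed: {sorted(allowed)}")
    rng = _rng(seed, "gas_profiles")
    rows, truths = [], []
    for i, regime in enumerate(regimes):
        site = f"site_{i:02d}"
        if regime == "biogenic":
            ratio = rng.uniform(1500, 6000)
            delta = rng.uniform(-95, -65)
            c1 = rng.uniform(1e5, 9.5e5)
        elif regime == "thermogenic":
            ratio = rng.uniform(2, 80)
            delta = rng.uniform(-45, -32)
            c1 = rng.uniform(1e3, 1e5)
        else:  # mixed: dry gas but heavy isotopes
            ratio = rng.uniform(1500, 6000)
            delta = rng.uniform(-45, -32)
            c1 = rng.uniform(1e4, 5e5)
        c2c3 = c1 / ratio
        c2 = 0.6 * c2c3
        c3 = 0.4 * c2c3
        c2plus = c2c3 * rng.uniform(1.0, 1.2)  # traces of C4+
        rows.append(
            dict(
                site_id=site,
                total_alkane_gas_ppm=c1 + c2plus,
                c2plus_ppm=c2plus,
                c1_ppm=c1,
                c2_ppm=c2,
                c3_ppm=c3,
                d13C_CH4_permil=delta,
            )
        )
        truths.append(dict(site_id=site, regime=regime))
    return (
        pd.DataFrame(rows, columns=["site_id", "total_alkane_gas_ppm", "c2plus_ppm",
                                    "c1_ppm", "c2_ppm", "c3_ppm", "d13C_CH4_permil"]),
        pd.DataFrame(truths, columns=["site_id", "regime"]),
    )


def gen_metabolite_matrix(
    n_compounds: int = 50,
    n_sites: int = 3,
    replicates: int = 5,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a compounds x samples intensity matrix with planted means.

    Per-site mean intensities are drawn log-normally per compound; each of
    the ``replicates`` technical replicates observes the mean under
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (0 gives identical replicates).  Returns ``(table, meta)``
    where meta carries sample->site/replicate maps, a compound->pathway map,
    and the planted per-site fractional abundances.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = _rng(seed, "metabolites")
    compounds = [f"cpd_{i:03d}" for i in range(n_compounds)]
    sites = [f"site_{i:02d}" for i in range(n_sites)]
    means = pd.DataFrame(
        rng.lognormal(mean=10.0, sigma=1.5, size=(n_compounds, n_sites)),
        index=compounds,
        columns=sites,
    )
    sigma = np.sqrt(np.log1p(noise_cv**2))
    data, sample_sites, sample_replicates = {}, {}, {}
    for site in sites:
        for r in range(1, replicates + 1):
            sample = f"{site}_r{r}"
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_compounds)) if sigma > 0 else 1.0
            data[sample] = means[site].to_numpy() * noise
            sample_sites[sample] = site
            sample_replicates[sample] = r
    table = pd.DataFrame(data, index=compounds)
    table.index.name = "compound"
    pathway_map = {c: METABOLITE_PATHWAYS[i % len(METABOLITE_PATHWAYS)] for i, c in enumerate(compounds)}
    meta = {
        "seed": int(seed),
        "sample_sites": sample_sites,
        "sample_replicates": sample_replicates,
        "pathway_map": pathway_map,
        "planted_fractions": means / means.sum(axis=0),
    }
    return table, meta


def gen_asv_counts(
    s_true: int,
    model: str = "geometric",
    depth: int = 10_000,
    seed: int = 0,
    param: float | None = None,
) -> tuple[pd.Series, dict]:
    """Multinomial community sample from a long-tailed rank-abundance model.

    ``model`` is ``"geometric"`` (p_i proportional to g**i, default g chosen
    so the tail spans ~4 orders of magnitude over s_true ranks) or
    ``"logseries"`` (p_i proportional to theta**i / i).  Returns the sampled
    count vector (length ``s_true``; undetected taxa are zeros) and truth.
    """
    if s_true < 1:
        raise ValueError("s_true must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ranks = np.arange(1, s_true + 1, dtype=float)
    if model == "geometric":
        g = param if param is not None else np.exp(np.log(1e-4) / max(s_true - 1, 1))
        weights = g ** (ranks - 1)
    elif model == "logseries":
        theta = param if param is not None else 0.999
        weights = theta**ranks / ranks
    else:
        raise ValueError(f"unknown abundance model {model!r}; use 'geometric' or 'logseries'")
    p = weights / weights.sum()
    rng = _rng(seed, "asv_counts")
    counts = rng.multinomial(depth, p)
    vec = pd.Series(counts, index=[f"asv_{i:04d}" for i in range(1, s_true + 1)], name="count")
    truth = {"seed": int(seed), "s_true": int(s_true), "model": model, "depth": int(depth)}
    return vec, truth


def write_fixture_dir(
    outdir: Union[str, Path],
    seed: int = 0,
    n_genomes: int = 12,
    spurious_rate: float = 0.2,
    n_sites: int = 3,
    gas_regimes: Union[str, Sequence[str]] = ("biogenic", "thermogenic", "mixed"),
    n_compounds: int = 50,
    replicates: int = 5,
    noise_cv: float = 0.2,
    s_true: int = 400,
    depth: int = 20_000,
) -> dict:
    """Write a complete synthetic study fixture directory plus truth.json.

    Emits hits.tsv, gas.tsv, metabolites.csv, metabolite_metadata.csv,
    asv_counts.tsv and truth.json under ``outdir``; returns the truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hits, hit_truth = gen_genome_hits(n_genomes, spurious_rate=spurious_rate, seed=seed)
    regimes = list(gas_regimes) if not isinstance(gas_regimes, str) else gas_regimes
    if not isinstance(regimes, str) and len(regimes) != n_sites:
        regimes = [regimes[i % len(regimes)] for i in range(n_sites)]
    gas, gas_truth = gen_gas_profiles(n_sites, regimes, seed=seed)
    metab, metab_meta = gen_metabolite_matrix(n_compounds, n_sites, replicates, noise_cv, seed=seed)
    asv, asv_truth = gen_asv_counts(s_true, depth=depth, seed=seed)

    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    gas.to_csv(outdir / "gas.tsv", sep="\t", index=False)
    metab.to_csv(outdir / "metabolites.csv")
    pd.DataFrame(
        {
            "compound": list(metab_meta["pathway_map"]),
            "pathway": list(metab_meta["pathway_map"].values()),
            "dual_pathway_flag": False,
        }
    ).to_csv(outdir / "metabolite_metadata.csv", index=False)
    asv.rename_axis("asv_id").reset_index().to_csv(outdir / "asv_counts.tsv", sep="\t", index=False)

    truth = {
        "seed": int(seed),
        "genome_hits": {
            "planted_counts": {g: row.to_dict() for g, row in hit_truth["planted_counts"].iterrows()},
            "presence": {g: {p: bool(v) for p, v in row.items()}
                         for g, row in hit_truth["presence"].iterrows()},
            "thresholds": hit_truth["thresholds"],
        },
        "gas": gas_truth.set_index("site_id")["regime"].to_dict(),
        "metabolites": {
            "sample_sites": metab_meta["sample_sites"],
            "planted_fractions": {s: metab_meta["planted_fractions"][s].round(12).to_dict()
                                  for s in metab_meta["planted_fractions"].columns},
        },
        "asv": asv_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
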