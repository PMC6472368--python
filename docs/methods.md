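# Methods

## Reaction energetics

Standard reaction energies are linear combinations of standard formation
values at T° = 298.15 K: ΔG° = Σᵢ νᵢ ΔGf°ᵢ and ΔH° = Σᵢ νᵢ ΔHf°ᵢ, with
νᵢ < 0 for reactants. Stoichiometric coefficients are stored as exact
rationals (`fractions.Fraction`), so fractional stoichiometries such as
12.25 or 0.5 are represented without floating drift and Hess-law identities
hold to rounding error of the final float sum (tested at 1e-9 kJ).

The bundled constants table (`data/formation_energies.tsv`) is compiled
from the standard microbial-bioenergetics references, with provenance per
row. Two conventions matter:

* **Proton**: ΔGf° = ΔHf° = 0 (1 M standard state); its activity is always
  10^(−pH) and never a free concentration.
* **Molecular hydrogen**: both the gas reference state (ΔGf° = 0) and the
  aqueous 1 M standard state (ΔGf° ≈ +17.6, ΔHf° ≈ −4.2 kJ/mol) are
  provided as distinct species. The bundled hydrogenogenic scenarios use
  the aqueous species: the published standard energy of hydrogenogenic
  hexadecane oxidation (1089.1 kJ) is reproduced only under that
  convention (the gas convention is 17.6 × 17 kJ lower), and an aqueous
  standard state is the natural choice when the varied quantity is a
  dissolved H₂ concentration.

Two constants are not available in the cited tables and are back-derived
with `derive_formation_energy` from printed reaction energies:
hexadecane(aq) ΔGf° = +49.47 kJ/mol (from the acetogenic-oxidation row;
it then predicts the complete-oxidation row to within 0.7 kJ) and benzoate
ΔHf° = −386.41 kJ/mol (from the complete-oxidation enthalpy; it predicts
the acetogenic-row enthalpy to within 1.2 kJ). The derived hexadecane ΔHf°
(−455.85 kJ/mol) is indistinguishable from the literature value for liquid
hexadecane, a useful consistency check.

**Unbalanced reactions.** `check_balance` reports exact element and charge
residuals (Σᵢ νᵢ·countᵢ; positive = product-side excess). Energy
computation deliberately proceeds on unbalanced reactions with a logged
warning rather than an error: the bundled acetogenic benzoate reaction is
printed in its source without the four waters needed for H/O balance
(residuals H +8, O +4), and the complete benzoate oxidation carries a
"3.755" sulfide coefficient, yet their printed energies match the printed
stoichiometries. Reproducibility of published numbers takes precedence;
the balance flag travels with every report row.

**Known irreproducibility.** The printed standard energy (120.9 kJ) and
in-situ energy (12.8 kJ) of hydrogenogenic benzoate oxidation cannot be
reproduced under either hydrogen convention with any single constants set
we tested (the computed values are 263.6 kJ aqueous / 210.8 kJ gas). The
reaction ships in the bundled file and participates in all qualitative
results (its feasibility at scavenged metabolite concentrations is robust
to the discrepancy), but its printed energies are excluded from numeric
reproduction checks. Similarly, the hydrogenogenic hexadecane in-situ
value carries a ~5 kJ residual (748.2 vs 753.3 kJ), tolerated at ±6 kJ.

## In-situ correction

Temperature correction uses the integrated Gibbs–Helmholtz relation at
constant reaction enthalpy, ΔG(T) = ΔG°·(T/T°) + ΔH°·(1 − T/T°) — the
standard approximation for small temperature offsets when heat-capacity
data are unavailable. Concentrations enter through RT·Σᵢ νᵢ ln aᵢ with
R = 8.314 J mol⁻¹ K⁻¹; water and other pure-liquid species contribute
nothing.

**Pressure policy.** The default deep-sea condition set records 300 atm but
applies no pressure term: the published in-situ energies are matched by the
temperature and activity corrections alone, and for dilute aqueous
reactions the ΔV correction over 300 atm is within the uncertainty of the
formation constants. An optional ideal-gas compression term
RT·ν_gas·ln(P) is available (`apply_pressure_term=True`) for reactions
with net gas-phase stoichiometry; it is off by default. No
ionic-strength/activity-coefficient model is applied: the 2 mM bicarbonate
condition is treated as an activity. Sulfate and sulfide default to
standard state; porewater values (e.g. 16–27 mM sulfate) can be supplied
as concentration overrides.

**Feasibility windows** exploit the fact that ΔG_in-situ is affine in
ln(concentration) of each varied species (slope νᵢRT): the surface is
evaluated once at the base condition and incremented analytically on a
log-spaced grid. The zero contour is located by sign change between
adjacent grid points with linear interpolation in log10 concentration —
exact for this affine surface up to the interpolation of the log-linear
crossing. Default conditions (4 °C, pH 8, 2 mM bicarbonate) reproduce the
syntrophy result: with dissolved H₂ at 1 µM and acetate at 2.5 µM, all
three standard-state-endergonic degradation scenarios become exergonic.

## Rule-based functional calling

Cutoffs are inclusive (e-value ≤, identity ≥, coverage ≥), matching the
conventions of the underlying search tools; the shipped defaults are
1e-18 + coverage 0.40 (CAZyme search), 1e-20 + 30 % identity (peptidase
and custom protein databases), and 1e-10 + 70 % identity (read-level
marker searches). "Genes detected" for a multi-gene pathway rule counts
*distinct gene families*, not raw hits, so duplicate hits to one enzyme
never satisfy a multi-gene rule. The pathway → family catalog
(`data/pathway_families.tsv`) follows standard KEGG module definitions and
is an editable input, not an assertion about any particular study's exact
lists; the multi-gene thresholds (EMP ≥5, beta-oxidation ≥3,
Wood–Ljungdahl ≥4, TCA ≥6, single markers ≥1) are the published calling
rules. A pathway present in the data but absent from the rule set is
called with the ≥1 rule and flagged.

Chao1 is implemented in both the classic form S_obs + F1²/(2F2) — which
raises when F2 = 0 rather than silently switching forms — and the
always-defined bias-corrected form S_obs + F1(F1−1)/(2(F2+1)); both are
cross-checked against scikit-bio's estimator in the test suite.

## Gas origin classification

Classification requires both lines of evidence to agree: Bernard ratio
> 1000 *and* δ¹³C-CH₄ < −60 ‰ for biogenic; ratio < 100 *and* δ¹³C >
−50 ‰ for thermogenic (the thermogenic band is the conventional
Bernard-diagram extension of the stated biogenic criterion; both bands are
configurable). Opposing evidence yields
"mixed"; a single line of evidence, or between-band values, yields
"indeterminate". Every call carries machine-readable evidence strings.
Published site ratios are treated as measured inputs; the C2/C3 split
behind them is not recomputed.

## Metabolomics normalization

Constant-sum normalization divides each sample column by its own total
("all observed metabolites" = all rows of the input table; no
pre-filtering). Zeros survive normalization and are floored only at the
log10 display step (default floor 1e-6 of total signal) — the log base and
zero-display convention are documented choices, not sourced values. The
replicate CV uses the sample (n−1) standard deviation. Compounds missing
from one replicate should be entered as zero intensity before
normalization.

## Synthetic data

Generators emulate the tabular layer the pipeline consumes, not sequence
data. One global seed fans out to fixed per-generator substreams
(`numpy` `SeedSequence` spawn keys), so outputs are bit-reproducible and
adding a generator never perturbs existing ones.

* Genome hit tables plant pathway gene sets whose distinct-family counts
  straddle the calling thresholds; decoy hits are drawn strictly outside
  the cutoffs (failing e-values at least one order of magnitude past the
  threshold, or identities below 30 %), which makes filter-then-call
  recovery exact by construction — passing these tests shows the rules and
  plumbing are correct, not that real annotation noise is this separable.
* Gas profiles are drawn inside the classification bands per regime
  (ratio 1500–6000 and δ¹³C −95…−65 for biogenic; 2–80 and −45…−32 for
  thermogenic; conflicting combinations for mixed), so classifier recovery
  on non-mixed regimes is exact.
* Metabolite matrices use log-normal per-compound site means (σ = 1.5 on
  the log scale) observed under multiplicative log-normal technical noise
  with chosen CV, in the 3-sites × 5-technical-replicates design; the
  noise is mean-preserving (σ² = ln(1+CV²), location −σ²/2).
* Community count vectors are multinomial draws from geometric or
  log-series rank-abundance models (the geometric default spans four
  orders of magnitude across ranks), giving the long-tailed undersampled
  communities in which Chao1 is informative.

What the synthetic data does not emulate: correlated annotation errors,
genome incompleteness and binning contamination, compositional coupling
between sites, chromatographic artifacts, or amplicon chimeras — recovery
results here validate the computations, not field performance.

## Problem sizes and determinism

The acceptance script runs the full pipeline at 25 synthetic genomes,
30 gas sites, a 50-compound × 15-sample metabolite matrix, and one
400-taxon community sampled to depth 5000 — sizes chosen so every stage
exercises its logic while the whole script completes in about a second.
All randomness flows from the single `--seed` argument. CLI manifests
contain input checksums, parameters and the package version but no
timestamps, so identical configurations produce byte-identical outputs.
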