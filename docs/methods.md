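# Methods

## The problem

Decomplexing ("bottom-up") venomics estimates the protein-family composition
of a snake venom by first separating the whole venom on reverse-phase HPLC,
then identifying the proteins of each collected fraction by LC-MS/MS of
tryptic digests. Because an *equal* protein mass (10 µg) of every fraction is
digested and injected regardless of how much of the venom that fraction
represents, spectral intensities are only comparable *within* a fraction; the
chromatogram carries the between-fraction information. The package implements
this two-level model end to end, plus the indirect-ELISA immunoprofiling used
to ask whether an antivenom actually recognises each fraction.

## Abundance model

For fraction *i* and protein *j*:

* **Chromatographic share** `f_i` — trapezoidal area of the baseline-corrected
  215 nm absorbance over the manually collected window `[start_i, end_i)`,
  normalised over collected windows only (baseline stretches between peaks are
  not part of the venom protein mass). `Σ f_i = 1`.
* **Within-fraction proportion** `p_ij = MSI_ij / Σ_j MSI_ij`, where
  `MSI_ij` (mean spectral intensity) is the mean of the peptide spectral
  intensities attributed to protein *j* in fraction *i*.
* **Whole-venom abundance** `a_ij = 100 · f_i · p_ij` percent of total venom
  protein. Collected fractions with no surviving identification contribute
  their whole share to an explicit *unidentified* bucket, so
  `Σ a_ij + unidentified = 100` holds identically (enforced to 1e-6 on
  computed tables; 0.5 on 2-dp transcribed tables).

A flat normalisation (`a_ij ∝ MSI_ij` over all fractions jointly,
`mode="global"`) is provided for comparison. It is *not* the default because
it contradicts the equal-mass digestion design and cannot represent
unidentified fractions; only the hierarchical model reproduces the structure
of fraction-resolved proteome tables, where each fraction's protein
percentages sum to the fraction's chromatographic percentage.

Duplicate rows of one accession within a fraction (distinct database entries
of the same protein) are pooled at the peptide level before the MSI is taken
(`merge_duplicates=True`, default). The unmerged mode keeps
(accession, protein name) granularity — PSM rows carry no finer sub-entry
key, so this is the finest reproducible split.

## PSM validation and FDR control

Identifications pass the fixed cascade **protein score > 20, peptide score
> 10, SPI > 70 %** (all strict inequalities: a protein score of exactly 20
fails, 20.01 passes) and are then thresholded on peptide score to an
estimated false discovery rate **< 1 %** among retained PSMs. The estimator
is the standard target–decoy ratio

```
fdr(c) = #decoys(score ≥ c) / max(1, #targets(score ≥ c))
```

smoothed into a q-value-style curve (running minimum over all cutoffs at or
below each candidate cutoff), which is monotone non-increasing and therefore
has a well-defined lowest admissible cutoff. Ties at the cutoff are
retained; decoys are removed from the output. FDR is controlled *after* the
score/SPI cascade by default (`filter_report` wires the stages in that
order), since the cascade changes the score population the estimate applies
to. Degenerate inputs: no decoys → warning, FDR reported as 0 and flagged;
no targets → `FdrUnattainable`.

## Chromatography numerics

Integration is trapezoidal on the sampled grid with interpolated window
endpoints; windows are half-open and non-overlapping, so boundary points are
never double-counted. On 0.1-min sampling this agrees with closed-form
Gaussian areas to well under 1 %. Two baseline estimators:
`linear_endpoints` (default; exact for linear solvent-gradient drift) and
`rolling_min`, a morphological opening (running minimum then maximum,
default 30-min window). The opening is exact on level offsets but lags on
steep ramps and eats into peaks wider than its window — the window default
therefore exceeds any realistic peak base (~9 min here). Negative corrected
absorbances are clipped to 0. `detect_peaks` (prominence default 2 mAU,
about 7 noise SDs) is a convenience for simulated traces; manually collected
boundaries are the reference workflow.

## ELISA immunoprofiling

The plate-wide blank mean is subtracted from every replicate, negatives
clipped to 0; cells are summarised as mean ± SEM (sd/√n, ddof = 1) of their
(typically 3) replicates. Classification uses the two empirically observed
absorbance regimes: **low** < 0.1, **reactive** ≥ 0.2, with `[0.1, 0.2)`
reported as *indeterminate* rather than forced to either side — the data
motivating the bands simply never fall there. Cross-antivenom comparison is
`100 · comparator / reference` per fraction, with the reference antivenom an
explicit required argument (the ratio direction is a convention, not a
fact), and a 0.02-absorbance floor on the reference below which the ratio is
flagged undefined instead of exploding on instrument noise. Control wells
(a heterologous venom antigen) are checked report-only: the same antigen is
a negative control for the homologous antivenom and a positive control for
the antivenom raised against it, so expectations are keyed by
(antigen, antivenom).

## Synthetic experiments

The generator emulates the study design so every stage has measurable ground
truth: ~9 toxin families with preset proportions (two presets mirror the two
geographic venom profiles, including one with two unidentified fractions
carrying 16.4 % of the venom), 2–5 proteoforms per family with a
Dirichlet(1.5) mass split, 12–16 Gaussian chromatographic peaks (σ = 1 min,
areas proportional to fraction shares, linear drift 0.02 mAU/min, white
noise 0.3 mAU), peptide counts Poisson(6), lognormal peptide intensities
(σ = 0.4, unit mean, scaled by the protein's within-fraction proportion and
then rescaled to a constant per-fraction total — the equal-mass convention),
target peptide scores N(35, 5), decoys N(15, 5) at 5 %, SPI ~ U(60, 100),
and triplicate ELISA wells with a saturating response
`A = 1.5·aff/(aff+0.25)` plus N(0, 0.03) noise over a 0.04 blank, truncated
at 0.

Realized FDR needs true/false labels among *target* PSMs (decoys never reach
the output), so the generator plants incorrect target matches at the decoy
rate with the decoy score distribution — the equal-rates assumption under
which the target–decoy estimator is calibrated. The hidden correctness
labels ride alongside the records and are not part of the serialisable
schema.

One seed drives everything: stage *k* draws from
`numpy.random.default_rng([seed, k])` (truth 0, chromatogram 1, PSMs 2,
ELISA 3, score benchmark 4) in a fixed order, so every artifact is
bit-reproducible.

What the simulation does **not** model: real peptide sequences and their
detectability/ionisation biases, retention-time structure within a fraction,
shared peptides between homologous proteoforms, protein-level score
dependence, plate edge effects. Passing recovery tests therefore shows the
*estimators* are correct under the stated noise model, not that real venoms
are quantified to the same accuracy.

## Problem sizes and tolerances in the test suite

Simulation-based checks use 20 seeds; the score-model FDR benchmark uses
2,000 PSMs per run (realized false-discovery proportion ≤ 2 % — twice the
nominal 1 %, the slack being binomial noise at this n); end-to-end family
recovery demands MAE < 2 percentage points per run (typical observed ≈ 0.5).
The ELISA recovery check compares cell means against the closed-form mean of
the zero-truncated response using a 3σ margin from the generator's *known*
noise (an SEM estimated from 3 replicates is t-distributed and too unstable
to define a 99.7 % margin, and it cannot see the shared blank-estimate
error). Transcribed reference values are asserted at their printed 2-dp
precision; computed conservation at 1e-6.

## Edge-case policy

* A collected fraction whose identifications are *all* removed by filtering
  is demoted to the unidentified bucket by the pipeline (with a warning) —
  operationally it is indistinguishable from a fraction that never yielded
  identifications. The low-level `whole_venom_abundance` stays strict and
  raises instead, so silent share loss cannot happen through the API.
* Abundance ties in sorted outputs break lexicographically (determinism).
* Unmapped accessions aggregate into `OTHER` with a warning, never silently.
* Readers reject exactly the inputs that violate a documented invariant,
  with the offending row in the message.

## Known limitations

Abundances are relative (percent of venom protein), not molar; proteoform
inference stops at accession identity; no cross-run intensity normalisation;
the ELISA module deliberately stops short of titration/EC50 fitting —
single-dilution immunorecognition is what the profile represents.
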