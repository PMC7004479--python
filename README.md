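# venomdecomplex

Fraction-resolved ("decomplexing") venomics quantification and antivenom
immunoprofiling, as a tested Python library with a command-line pipeline.

It is written for venom proteomics groups who run the standard bottom-up
workflow — whole venom separated on C18 reverse-phase HPLC, each collected
fraction digested with trypsin at equal mass and identified by LC-MS/MS —
and who then need defensible numbers: per-protein and per-family relative
abundances, non-redundant protein counts, a two-venom comparison, and
ELISA-based immunorecognition profiles of candidate antivenoms.

## The model

Because an equal protein mass of every fraction is digested, spectral
intensities are only comparable *within* a fraction; the chromatogram carries
the between-fraction weights. Whole-venom abundance is therefore
hierarchical:

* `f_i` — share of fraction *i*: its trapezoidal 215 nm peak area over the
  total area of all collected fractions (after baseline correction);
* `p_ij = MSI_ij / Σ_j MSI_ij` — protein *j*'s mean spectral intensity (mean
  of its peptide intensities) relative to the fraction total;
* `a_ij = 100 · f_i · p_ij` — percent of total venom protein. Fractions with
  a share but no identification feed an explicit *unidentified* bucket, so
  everything sums to 100 by construction.

Upstream, peptide-spectrum matches pass the strict cascade
`protein score > 20`, `peptide score > 10`, `SPI > 70 %`, then a
target–decoy FDR filter (`#decoys ≥ c / #targets ≥ c`, q-value smoothed)
keeps the estimated PSM-level FDR below 1 %. Downstream, ELISA plates are
blank-corrected, summarised as triplicate mean ± SEM, classified against the
empirical absorbance regimes (low < 0.1, reactive ≥ 0.2), and compared
across antivenoms as percent of a declared reference.

A fully deterministic synthetic-experiment generator (chromatogram, PSM
tables with decoys and hidden correctness labels, ELISA plates) provides
ground truth for every stage; see `docs/methods.md` for the model, defaults
and what the simulation does and does not capture.

## Worked example

The package ships a per-protein transcription of a published comparative
proteome of Russell's viper (*Daboia siamensis*) venoms from Thailand and
Indonesia, with family assignments:

```python
import venomdecomplex as vd

thai, indo, fmap = vd.load_reference_proteomes()
comp = vd.compare_venoms(thai, indo, fmap)
print(comp.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
```

```
 family  abundance_a_pct  abundance_b_pct  delta      status
   PLA2            37.92            48.37 -10.45      shared
   SVSP            18.07            22.41  -4.34      shared
   KSPI            22.38             0.00  22.38 unique_to_a
snaclec            10.63             1.03   9.60      shared
    DIS             0.00             6.21  -6.21 unique_to_b
 svVEGF             5.42             0.00   5.42 unique_to_a
   SVMP             3.04             2.15   0.89      shared
   5NUC             1.85             0.18   1.67      shared
   LAAO             0.00             1.47  -1.47 unique_to_b
  svNGF             0.52             0.85  -0.33      shared
    PDE             0.16             0.89  -0.73      shared
```

Each row is a toxin family's percent of total venom protein in venom A
(Thailand) and B (Indonesia); phospholipase A2 dominates both venoms, the
Kunitz-type inhibitors (22.38 %) and venom VEGF exist only in the Thai
venom, and L-amino-acid oxidase and disintegrin only in the Indonesian one.
Non-redundant counts come from the same tables:

```python
vd.count_nonredundant(thai, fmap)   # {'proteins': 47, 'families': 9, ...}
vd.count_nonredundant(indo, fmap)   # {'proteins': 25, 'families': 9, ...}
```

The same functions run on real inputs (trace CSV, boundary TSV, PSM TSV,
family map, ELISA CSV) or on simulated ones:

```bash
venomdecomplex simulate --preset indo-like --seed 4 --out sim/
venomdecomplex filter --psms sim/psms.tsv --out sim/filtered.tsv
venomdecomplex quantify --trace sim/trace.csv --boundaries sim/boundaries.tsv \
    --psms sim/filtered.tsv --family-map sim/family_map.tsv \
    --unidentified F3,F10 --out-prefix sim/indo
venomdecomplex immunoprofile --plate sim/elisa.csv --reference DsMAV --comparator SABU
```

or as one configured run (`venomdecomplex run --config run.yml --out out/`),
which writes per-venom protein/family tables, the comparison JSON, the
immunoprofiles and a run log, byte-identically on re-runs.

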