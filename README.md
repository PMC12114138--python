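# oglyco

A tested, reusable pipeline for O-glycopeptide identification and
O-glycosylation-site localization on CTP-fusion glycoproteins, plus released
2-AB-labeled O-glycan profiling:

* **`oglyco.masses`** — monoisotopic mass arithmetic for peptides, glycan
  compositions, 2-AB derivatives, glycopeptides and fragment ions.
* **`oglyco.digest`** — in-silico OpeRATOR + sialidase digestion: every
  product starts at a glycan-occupied Ser/Thr; specific and semi-specific
  modes, missed cleavages, glycoform enumeration (full or partial site
  occupancy).
* **`oglyco.fragments`** — theoretical HCD (b/y) and EThcD (c/z) ions with
  glycan-retaining, HexNAc-remnant and naked states, oxonium ions, and
  ppm-tolerance peak matching.
* **`oglyco.localize`** — tiered site evidence (`direct_bracketing` >
  `single_candidate` > `remnant_localized` > `enzyme_inferred` >
  `ambiguous`) and aggregation into a protein site table with novelty
  flagging.
* **`oglyco.search`** — closed-search identification of spectra against the
  enumerated candidate space.
* **`oglyco.profile`** — chromatogram peak assignment (isomers by
  retention-time window; peeling and deacetylation byproducts), normalized
  peak-area percentages, replicate RSD, dilution-series linearity and
  recovery rates.
* **`oglyco.simulate`** — fully seeded synthetic spectra and area tables
  with ground truth, including the bundled FSH-CTP preset (28-residue CTP
  region numbered 112–139, sixteen observed core-1 glycopeptides).
* **`oglyco.io` / `oglyco.cli`** — FASTA, MGF and CSV peak tables; a click
  CLI binding the stages together.

## CLI

```bash
# digestion products for two glycosites, no missed cleavages
oglyco digest --preset fsh-ctp --sites 126,134 --max-missed 0

# seeded synthetic dataset (MGF spectra + truth + profile CSV tables)
oglyco simulate --preset fsh-ctp --seed 7 --out-dir synthetic/

# identify + localize spectra into a protein site table
oglyco localize --preset fsh-ctp --sites 114,115,121,124,126,132,134 \
    --mgf synthetic/spectra.mgf --out site_table.tsv

# released-glycan quantitation report from a peak table CSV
oglyco profile --peaks synthetic/profile_dilution.csv --out report.tsv

# everything end to end
oglyco run-all --preset fsh-ctp --seed 7 --out-dir run/
```

Every report starts with a provenance header recording the configuration
(tolerances default to 10 ppm precursor / 20 ppm fragment / 0.02 Da profile;
z-dot ion convention; up to three missed cleavages).

## Conventions

* All protein coordinates are 1-based and inclusive; the FSH-CTP preset
  numbers the region 112–139.
* Charging uses the proton mass (1.0072765 Da); peptide "neutral mass" is
  residues + water.
* 2-AB labeling is modeled as a net +120.068748 Da on the free reducing
  glycan; mono-deacetylation subtracts one acetyl (42.010565 Da).
* z ions default to the radical z+1 ("z-dot", y − 16.01872) convention,
  configurable to plain z or z+1.
* Missed cleavages count glycan-occupied internal sites: an unoccupied
  candidate Ser/Thr is not a cleavage opportunity for the enzyme.
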