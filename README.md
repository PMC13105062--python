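# snaparray

Analysis toolkit for high-density genomic **SNAP** (Specificity and Affinity
for Protein) DNA-binding microarrays — experiments in which a purified
transcription factor is bound to hundreds of thousands of double-stranded
probes tiled across its ChIP-seq regions, so that motif recognition,
mismatch tolerance, flanking-sequence effects and dimeric-site geometry can
be measured on naked DNA, free of chromatin and cofactors.

The package is written for computational biologists analyzing such arrays
(the shipped defaults target a Grainyhead-family factor recognizing the
palindromic octamer 5'-AACCGGTT-3') and covers the full desk side of the
experiment:

- **probe design** — 48-mer probes tiled at 6-bp steps across genomic
  regions, plus control libraries: all C(8,k)·3^k k-mismatch permutations
  of the consensus, dimer spacing series (0–32 bp, forward-forward and
  reverse-forward), dimer mismatch combinations, and 25-bp hairpins;
- **normalization** — per-replicate global scaling, quantile normalization,
  and per-probe median collapse of triplicates into one intensity;
- **motif and mismatch analysis** — motif/IUPAC scanning on both strands,
  strand-canonical mismatch bookkeeping for the palindromic consensus,
  ranked FASTA export for external motif discovery, flanking-base quartile
  enrichment with chi-squared tests, and Sequence Specificity Landscapes
  (concentric mismatch rings with a flattened one-mismatch ring);
- **helical phasing** — a DNA torsional-elasticity model of dimeric binding
  versus motif spacing, with four-parameter nonlinear least-squares fitting;
- **occupancy classification** — collapse of tiled probes into regions,
  direct versus indirect (cofactor-tethered) classification, distinct-site
  counting, and differential cofactor-association tests;
- **synthetic data** — a simulator that generates genomes, probe libraries
  and raw triplicate intensities with recorded ground truth, so the whole
  pipeline runs and is tested without any external data.

## The phasing model

For probes carrying two motifs separated by `s` bases, fluorescence
oscillates with `s` because both sites must present on compatible
rotational faces of the helix. The model places phasing minima at
`s_min + n·h_r` and broadens them with thermal twist fluctuations:

```
F(s) = [ Σ_{n=-N}^{N} K_min⁻¹ exp( -(s - (s_min + n·h_r))² / (2 σ_TW(s)²) ) ]⁻¹

σ_TW(s) = √s · σ_bp,     σ_bp = (h_r / 2π) · √(ℓ k T / C_app)
```

with `h_r` the helical repeat (bp/turn), `K_min` the effective binding
strength at a phasing minimum, `C_app` the apparent torsional modulus
(erg·cm), `ℓ` the rise per base pair (3.4×10⁻⁸ cm), `k` Boltzmann's
constant, `T` the temperature, and `N = 96` summation truncation.
`fit_phasing` recovers `(h_r, C_app, K_min, s_min)` by bounded least
squares with multi-start initialization over `h_r` (the objective is
multimodal in the period).

## Worked example

Fitting the phasing model to a simulated dimer spacing series
(`python examples/05_phasing_fit.py`):

```
recovered helical repeat h_r = 5.4596 bp (simulated at 5.46)
s_min = 1.001 bp, K_min = 0.998, sigma_bp = 0.1500 bp
converged: True, residual sum: 0.0239 (32 spacings used)
```

The fit recovers the ~5.5-bp periodicity — about half the 10.5-bp B-DNA
helical repeat — from noisy fluorescence spanning many orders of magnitude;
`sigma_bp` is the per-base twist standard deviation implied by the fitted
torsional modulus.

End-to-end classification on a synthetic array
(`python examples/06_classify_regions.py`):

```
11922 probes collapsed into 300 regions: 146 direct, 154 indirect (51.3% indirect)
FoxA1: 21% of direct vs 55% of indirect regions, chi2 = 36.5, p = 1.57e-09
ERa half-site: 47% of direct vs 47% of indirect regions, chi2 = 0.0, p = 9.30e-01
```

Regions whose strongest probe exceeds normalized intensity 3.0 are *direct*
binding regions; the rest are *indirect* (occupied in cells but silent on
naked DNA, implying recruitment through a tethering partner). The planted
FoxA1-site enrichment in the indirect class is detected; the ERα half-site,
planted at equal rates, shows none.

Each script in `examples/` demonstrates one capability and prints what it
computes; a thin CLI (`snaparray design|simulate|normalize|scan|flank|ssl|
phasing|classify|report`) wraps the same library functions for shell use.

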