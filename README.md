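# pcpquant

Quantification of **epidermal planar cell polarity (PCP)** from fluorescence
microscopy. The package turns four common read-outs of tissue polarity into
reproducible, tested measurements:

1. **Hair-follicle polarity** — from two-channel images of a developing
   backskin (P-cadherin marking the anterior follicle core, Sox9 the
   posterior domain), classify each follicle as polarized (offset Sox9
   crescent) or unpolarized ("bicycle-wheel" Sox9 ring), measure the growth
   angle of polarized follicles, and summarize a tissue as a cumulative
   polarized percentage plus a rose-plot histogram of angles
   (anterior = 0°, posterior = 180°).
2. **Per-cell nematic order** — the axis and magnitude of membrane-protein
   polarity for each cell of a segmented epithelium, from the
   intensity-weighted second circular moment of the cell's boundary pixels:

   *Q* = Σₚ *I*ₚ e^(2 i φₚ) / Σₚ *I*ₚ,  magnitude = |*Q*| ∈ [0, 1],
   axis = arg(*Q*)/2 ∈ [0°, 180°).

3. **Junction enrichment (JE)** — the ratio of mean fluorescence along a
   cell–cell junction to the mean over the participating cell(s), after
   background subtraction; distributions of JE scores are compared with the
   two-sample Kolmogorov–Smirnov test.
4. **FRAP kinetics** — background/acquisition-bleach correction and
   full-scale normalization, (Fₜ − F_bleach)/(F_ini − F_bleach), of recovery
   traces; one-phase association fits
   Y(t) = Y0 + (Plateau − Y0)(1 − e^(−kt)); and the immobile fraction
   1 − (Plateau − Y0)/(1 − Y0).

Because real acquisitions of this kind are rarely shareable, the package
ships a first-class **synthetic-data module** that generates each input type
with known ground truth (follicle angles, per-cell polarity, enrichment
factors, mobile fractions), so every stage is validated end-to-end by
recovery tests.

Intended users: imaging labs quantifying epithelial polarity phenotypes who
want scripted, seed-reproducible numbers instead of interactive ROI work.

## Worked example

Simulate a small backskin (20 follicles, 70 % polarized on average, SNR ≈ 10)
and quantify it:

```bash
cat > follicles.json <<'EOF'
{"image_size": [800, 800], "n_follicles": 20, "polarized_fraction": 0.7,
 "angle_concentration": 4.0, "noise_sd": 20.0, "background_level": 50.0}
EOF
pcpquant simulate follicles --config follicles.json --seed 11 --outdir sim
pcpquant follicles --image sim/follicles.tif --out out
```

prints

```
17/20 follicles polarized (85.0%)
```

and `out/follicle_summary.csv` contains

```
n_total,n_polarized,pct_polarized,circular_mean_deg,circular_resultant
20,17,85.0,353.78123153962474,0.8554157571748816
```

The generator's ground truth for this seed is 17/20 polarized with a true
circular mean of 353.9°: the pipeline recovered the polarized count exactly
and the mean orientation to 0.1°. (17/20 = 85 % rather than 70 % is the
binomial draw at n = 20, not an analysis bias.) A circular resultant of 0.86
says the polarized follicles point coherently toward the anterior
(0° ≈ 354°), as drawn from the von Mises distribution with κ = 4.

A FRAP example on 20 noisy traces with a true mobile fraction of 0.6
(immobile 0.4) and k = 0.02 s⁻¹:

```bash
cat > frap.json <<'EOF'
{"mobile_fraction": 0.6, "rate_k": 0.02, "n_traces": 20, "noise_sd": 20.0}
EOF
pcpquant simulate frap --config frap.json --seed 11 --outdir simf
pcpquant frap --traces simf/frap_traces.csv --out outf
```

prints

```
immobile fraction 0.407, k = 0.0199/s, r^2 = 0.9984
```

— the pooled fit of the averaged trace recovers the immobile fraction within
0.01 and the rate within 1 %.

The other stages work the same way
(`pcpquant simulate {mesh|pairs} …`, `pcpquant polarity …`,
`pcpquant je …`, `pcpquant je-compare …`); every command writes CSV outputs
plus a `run_config.json` sidecar recording the resolved parameters.

## Layout

```
src/pcpquant/
  synthetic.py   fixture generators + ground truth
  follicles.py   follicle segmentation / classification / summaries
  polarity.py    per-cell nematic order and tissue aggregation
  junctions.py   background correction, JE scoring, KS comparison
  frap.py        trace correction, normalization, fitting, immobile fraction
  geometry.py    angle conventions and circular statistics
  io.py          TIFF / ROI-JSON / CSV readers and writers, config
  cli.py         the pcpquant command-line interface
docs/methods.md  models, conventions, parameter choices, limitations
```
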