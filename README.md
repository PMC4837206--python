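# ramanstack

Depth-resolved analysis of confocal Raman Z-stacks of the vessel wall:
separate the endothelium from the media, quantify lipid and protein
marker bands, and compare control against metastasis-bearing groups —
with a synthetic phantom generator so that every stage of the pipeline
can be validated against known ground truth.

## The problem

Confocal Raman imaging of an en face artery (endothelium facing the
objective) yields a Z-stack: a grid of Raman spectra at each of several
focal depths, 0.5 μm apart. The single-cell endothelial lining occupies
only the topmost plane(s); the smooth-muscle media lies below. Because
endothelial dysfunction — e.g. under metastatic disease — chemically
alters the endothelium but not the media, the analysis must resolve
composition *per layer* rather than over the bulk tissue.

The composition statistic is the **lipid-to-protein ratio**

```
R = I(2940 cm⁻¹) / I(1007 cm⁻¹)
```

where I(·) is the integral intensity of a marker band in the per-plane
average spectrum: the CH-stretch envelope at 2940 cm⁻¹ (lipids +
proteins) and the phenylalanine ring-breathing band at 1007 cm⁻¹
(protein marker). Integration windows and normalization regions are
dialect-specific (formalin-fixed dried tissue vs fresh tissue in
buffer):

| dialect | baseline | normalization | 2940 window | 1007 window |
|---|---|---|---|---|
| fixed   | `poly2`     | 450–3200 cm⁻¹ | 2825–3030 cm⁻¹ | 993–1023 cm⁻¹ |
| unfixed | `autopoly2` | 200–1500 cm⁻¹ | 2820–3012 cm⁻¹ | 997–1016 cm⁻¹ |

The pipeline stages are:

1. **phantom** — generate synthetic vessel-wall stacks (Gaussian marker
   bands, fluorescence baseline, shot-like noise, cosmic-ray spikes,
   depth attenuation) with full ground truth;
2. **spectra_io** — plain-text cube format (one TSV per plane +
   `cube.json`), bit-stable round-trips;
3. **preprocess** — cosmic-ray removal → degree-2 polynomial baseline
   correction → region-restricted vector normalization, per pixel;
4. **depth_profile** — designate the brightest plane Z = 0, label planes
   upper (endothelium) / lower (media), drop unmeasurably dim planes,
   integrate marker bands on average spectra, form R;
5. **stats_compare** — per-compartment group comparison: mean ± SEM,
   two-sided two-sample t-test (Welch by default), percent change,
   significance at p < 0.05.

## Worked example

A complete run from a YAML configuration (here with phantom inputs for
both groups; real cube directories can be listed instead via `cubes:`):

```yaml
# run.yaml
dialect: fixed
seed: 7
alpha: 0.05
conditions:
  control:    {n_measurements: 3, phantom: {plane_grid: [6, 6], n_planes: 3}}
  metastasis: {n_measurements: 3, phantom: {plane_grid: [6, 6], n_planes: 3}}
```

```sh
ramanstack run -c run.yaml -o out/
```

writes `comparison.tsv`, `report.md`, per-stack ratio tables, `run.log`
and a resolved-config snapshot. The report for the run above:

| compartment | measure | control | metastasis | Δ% | p |
|---|---|---|---|---|---|
| upper | I(2940 cm⁻¹) lipid+protein CH | 12.59 ± 0.031 (n=3) | 12.5 ± 0.0126 (n=3) | -0.8% | 0.075 |
| upper | I(1007 cm⁻¹) phenylalanine | 0.4357 ± 0.0162 (n=3) | 0.5134 ± 0.009 (n=3) | +17.8% | 0.0226 * |
| upper | lipid/protein ratio | 28.99 ± 1.14 (n=3) | 24.36 ± 0.438 (n=3) | -16.0% | 0.042 * |
| lower | I(2940 cm⁻¹) lipid+protein CH | 12 ± 0.0118 (n=3) | 11.97 ± 0.0117 (n=3) | -0.2% | 0.176 |
| lower | I(1007 cm⁻¹) phenylalanine | 1.122 ± 0.00579 (n=3) | 1.118 ± 0.0017 (n=3) | -0.4% | 0.556 |
| lower | lipid/protein ratio | 10.69 ± 0.0447 (n=3) | 10.71 ± 0.00677 (n=3) | +0.1% | 0.779 |
| all | I(2940 cm⁻¹) lipid+protein CH | 12.2 ± 0.0113 (n=3) | 12.15 ± 0.0111 (n=3) | -0.4% | 0.0342 * |
| all | I(1007 cm⁻¹) phenylalanine | 0.8933 ± 0.00923 (n=3) | 0.9165 ± 0.00254 (n=3) | +2.6% | 0.12 |
| all | lipid/protein ratio | 16.79 ± 0.41 (n=3) | 15.26 ± 0.145 (n=3) | -9.1% | 0.0519 |

Reading it: the phantom plants a +18 % endothelial protein increase and
a −4 % lipid decrease in the metastasis group. The pipeline finds the
protein increase (+17.8 %, significant) confined to the upper
compartment — the endothelium — while the media (lower) is unchanged,
and the lipid/protein ratio drops accordingly. The small shortfall from
the planted +18 % is the vector-normalization coupling discussed in
`docs/methods.md`.

Each stage is also available standalone (`ramanstack phantom`,
`preprocess`, `profile`, `compare`) on the documented file formats, and
as library functions (`ramanstack.generate_stack`, `preprocess_stack`,
`profile_stack`, `compare_conditions`, ...).

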