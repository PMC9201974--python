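# phantomqc

Qualification pipeline for 3D-printed tissue-simulating fluorescence
phantoms.

Printed phantoms that mimic the optical properties of tissue (reduced
scattering μs′ ≈ 9–10 cm⁻¹, absorption μa ≈ 0.06–0.1 cm⁻¹ in the NIR)
are used as stable reference objects for fluorescence-guided-surgery
imagers. Before a phantom can serve as a reference it has to be
qualified: its optical properties verified by time-domain transmittance
spectroscopy, its spatial homogeneity mapped, its fluorescence output
checked for stability and photobleaching, and its dye loading placed on
the linear part of the concentration response. `phantomqc` implements
that chain end to end, together with synthetic-data generators that
make every analysis step testable as ground-truth recovery.

## What is in the box

| Module | Purpose |
| --- | --- |
| `phantomqc.transport` | White (zero-absorption) Monte Carlo photon transport through a slab, an absorbing validation variant, and a closed-form time-domain diffusion oracle |
| `phantomqc.inversion` | White lookup-table construction, analytic absorption scaling, IRF convolution, fit-window selection and Poisson-weighted LUT fitting of measured DTOFs to (μs′, μa) |
| `phantomqc.mapping` | Scan-grid integral maps, per-position property maps, and central-region homogeneity statistics |
| `phantomqc.imaging_qc` | Mean-of-21-brightest ROI statistic, series normalization, stability metrics, exponential bleaching fits |
| `phantomqc.spectra` | Linear background subtraction, sub-sample peak localization, long-pass band intensity, linearity-onset detection, equivalent-concentration lookup |
| `phantomqc.synthetic` | Generators for DTOFs, scan grids, imager frame stacks and dye spectra — each returns its ground truth |
| `phantomqc.io` | CSV / HDF5 / TIFF / YAML round trips and report export |
| `phantomqc.cli` | `phantomqc` command-line entry point wrapping the above |

The physical model: the "white" Monte Carlo method simulates photon
transport once at μa = 0; absorption for any μa is then applied
analytically as exp(−μa·c·t), which is exact because the photon path
length equals c·t. A measured distribution of times of flight (DTOF)
is inverted by convolving lookup-table entries with the instrument
response function (IRF), applying candidate absorption, and minimizing
a Poisson-weighted χ² over the table.

## Worked example

Generate a synthetic measured DTOF (truth μs′ = 9.5 cm⁻¹,
μa = 0.08 cm⁻¹, 10⁶ counts, 35-ps IRF), build a lookup table and invert:

```
$ phantomqc synth --what dtof --seed 7 -o data
wrote dtof dataset to data
$ phantomqc lut --grid-min 8 --grid-max 11 --grid-step 0.1 --engine diffusion -o lut.h5
31 entries -> lut.h5
$ phantomqc fit --lut lut.h5 --dtof data/dtof.csv -o fit.json
mu_sp=9.484 mu_a=0.0797 -> fit.json
```

`fit.json` holds the full result:

```json
{
  "mu_sp": 9.484449008995966,
  "mu_a": 0.07972322814669555,
  "amplitude": 35399320.53097269,
  "chi2_reduced": 0.9382424700714195,
  "window": [39, 261],
  "converged": true,
  "grid_index": 15,
  "low_counts": false
}
```

The same operations are available as library calls
(`build_lut`, `fit_dtof`, `integral_map`, `central_stats`,
`stability_metrics`, `fit_bleaching`, `linearity_onset`, ...); see the
docstrings and `docs/methods.md`.

## Documentation

`docs/methods.md` describes the physical model, the numerical choices
(time quantization, boundary sampling, fit weighting), all default
parameters with their rationale, and the known limitations of the
synthetic generators.
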