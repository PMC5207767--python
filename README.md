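# cymage

Quantification of single-molecule TIRF movies of fluorescently labelled
membrane proteins — the analysis used to show that cyanine-dye amino acids
(Cy3/Cy5 conjugated to a phenylalanine analogue, delivered by misacylated
suppressor tRNA) are genuinely incorporated into ion channels at the cell
surface. It is written for single-molecule microscopists and genetic-code
-expansion labs who need the full chain from raw two-channel TIFF stacks
to per-oocyte statistics, and for methods developers who want each stage
testable against exact ground truth.

The package answers three questions about a pair of Cy3/Cy5 image stacks:

1. **How many spots per µm² of membrane?** Rolling-ball background
   subtraction (morphological opening with a ball of radius 50 px),
   threshold/area detection of 7×7 areas of interest (AOIs) on the first
   frame, count / area.
2. **How many fluorophores per spot?** Integrated-intensity traces per AOI
   and automated photobleaching step counting: the number of irreversible
   downward steps before complete photo-destruction bounds the number of
   labelled subunits. Steps are found by an exactly solved penalized
   change-point fit, `SSE + λσ²log T · k` with a per-step amplitude gate
   of `2σ`, and traces with upward transitions or a non-zero final level
   are rejected — an explicit, reproducible replacement for manual
   classification.
3. **Do the two colours co-occur beyond chance?** Cy5 AOIs mapped onto the
   Cy3 field (1–2 px registration offset), colocalized fraction within a
   2 px Chebyshev tolerance, against an empirical null built by rotating
   the Cy5 pattern 90° about the image center. For random (CSR) channels
   the expected fraction is `1 − exp(−λ(2r+1)²·px²)`.

Because the study's raw oocyte stacks are not deposited, `cymage.simulate`
generates two-channel movies with known ground truth (Poisson spot
placement at the reported densities, 1–5 fluorophores per spot,
exponential bleaching, Gaussian PSF, EMCCD-like noise, imperfect channel
registration); everything downstream is validated against that truth. The
closed-form quantifications from the same study are in `cymage.quantify`:
tRNA acylation efficiency `A_dye·ε_RNA/(A_RNA·ε_dye)·100`,
percent-of-control luminescence, fold-over-background currents with
delta-method errors, decay-to-10% kinetics (`τ·ln 10` for an exponential),
the equal-variance two-tailed t-test, and hierarchical per-oocyte
mean ± s.e.m.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate one encoded-condition movie pair and run the full analysis from
the shell (the library equivalents live in `cymage.pipeline`):

```sh
$ cymage simulate --preset encoded --out demo --seed 11 --frames 100 --size 96
$ cymage subtract --in demo/cy3.tif --out demo/c3.tif --radius 50
$ cymage subtract --in demo/cy5.tif --out demo/c5.tif --radius 50
$ cymage detect --in demo/c3.tif --out demo/a3.csv --channel Cy3
45 AOIs, 0.1221 spots/um^2 -> demo/a3.csv
$ cymage detect --in demo/c5.tif --out demo/a5.csv --channel Cy5
19 AOIs, 0.0515 spots/um^2 -> demo/a5.csv
$ cymage steps --in demo/c3.tif --aois demo/a3.csv --out demo/steps.csv
45 traces, 29 accepted -> demo/steps.csv
$ cymage coloc --cy5 demo/a5.csv --cy3 demo/a3.csv --dims 96x96 --offset 1,2
{"n_cy5": 19, "n_colocalized": 4, "fraction": 0.21052631578947367, "null_fraction": 0.10526315789473684}
```

Reading the numbers: the generator placed Cy3 spots at 0.14/µm² and Cy5 at
0.08/µm²; detection recovers 0.122 and 0.052 on this movie (connected
-component detection merges near neighbours, and single movies are noisy —
the per-oocyte aggregation in `cymage.pipeline` is the quantitative path).
Of 45 Cy3 traces, 29 bleach cleanly to baseline and their step counts
{1: 9, 2: 9, 3: 6, 4: 2, 5: 2, 7: 1} reflect the preset's multi-label
distribution; the 16 rejected traces either never reached baseline within
100 frames or showed an upward (blinking-like) transition. 4 of 19 Cy5
spots have a Cy3 partner within 2 px (21%); rotating the Cy5 pattern 90°
still leaves 10.5% "colocalized" by chance at these densities, which is
why the null is always reported alongside.

A single closed-form example: luminescence of 466 ± 85 AU for the
dye-charged tRNA versus 826 ± 126 AU for the phenylalanine control is

```python
>>> from cymage.quantify import percent_of_control
>>> percent_of_control(466, 826, ndigits=0)
56
```

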