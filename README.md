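# kinetoquant

Quantification of kinetochore and pericentromeric fluorescence signals in
mitotic cells.

During mitosis the chromosomal passenger complex (CPC — Aurora B kinase with
INCENP, survivin and borealin) concentrates at the pericentromere, and the
spindle-assembly-checkpoint kinase MPS1 is recruited to kinetochores.
Experiments probing this machinery measure three kinds of quantities from
multi-channel fluorescence images of fixed mitotic cells:

1. **Spot-level recruitment** — how much of a protein (e.g. MPS1) sits at
   each kinetochore, relative to a constitutive kinetochore marker
   (CENP-C or NDC80), after local background correction;
2. **Region-level signals** — chromatin-associated or pericentromeric
   intensity per cell (Aurora B, borealin, survivin, H3pS10), corrected by
   cytoplasmic background and normalized to DNA staining;
3. **Distances** — inter-kinetochore (KT–KT) separations, which report on
   biorientation tension, and intra-kinetochore marker offsets, both from
   sub-pixel Gaussian fits to line profiles across super-resolution (STED)
   images.

`kinetoquant` implements these pipelines as a tested Python library, together
with the nonparametric statistics used to compare conditions and a synthetic
scene generator that provides exact ground truth, so every stage can be
validated without access to raw microscope data.

## The core procedures

**Kinetochore recruitment** (per cell): a binary kinetochore mask is computed
as a white top-hat of the reference channel (disc radius 5 px) thresholded by
the iterative-intermeans (isodata) rule `t ← (mean(v ≤ t) + mean(v > t))/2`.
The 20 brightest non-overlapping top-hat maxima receive 8 px-diameter
circular ROIs (exactly 52 lattice pixels under the corner-centered
rasterization). For each spot, a background ROI of the same 52-pixel size is
accrued radially from the nearest pixels outside both the spot ROI and the
kinetochore mask. Per channel, `corrected = max(ROI mean − background mean, 0)`,
and the recruitment ratio is `corrected(channel) / corrected(reference)`,
averaged over the cell's kinetochores.

**Region signals**: chromatin mask from the isodata-thresholded DNA channel
(largest connected component); cytoplasm mask from the cell extent minus the
dilated chromatin. CPC/Aurora-class channels are corrected by the mean
cytoplasmic signal (negatives clipped to zero), H3pS10-class channels are
not; all are normalized by the mean DNA signal and scaled to the control
condition's mean.

**Distances**: 1 px-wide line profiles with bilinear interpolation, all
channels sampled at identical coordinates. Spot positions are refined by
fitting `offset + A·exp(−(x−μ)²/2σ²)` along the inter-spot axis; KT–KT
distance is the Euclidean distance between refined centers × pixel size, and
intra-kinetochore distance is |μ₁ − μ₂| between two markers fitted on the
same profile.

**Statistics**: two-tailed unpaired Student's t-tests for distances (each
kinetochore pair a replicate); Kruskal–Wallis plus Dunn's post hoc z-tests
with Bonferroni correction over planned comparisons for recruitment assays
(each cell a replicate); significance stars ns/*/**/***/**** at
0.05/0.01/0.001/0.0001.

## Worked example

`examples/01_kinetochore_recruitment.py` renders two control and two
"depleted" cells (measured channel at 20% of control amplitude), runs the
default per-cell pipeline and scales to the control mean:

```
ctrl_0: n_kinetochores=20 mean ratio=0.978
ctrl_1: n_kinetochores=20 mean ratio=0.985
depleted_0: n_kinetochores=20 mean ratio=0.204
depleted_1: n_kinetochores=20 mean ratio=0.199

Scaled to control mean (control == 1.0 by construction):
ctrl        1.000000
depleted    0.205504
```

Each cell contributes exactly 20 kinetochores; the recruitment ratio of the
depleted cells recovers the true 0.2 depletion factor to within a few
percent. The other examples cover region-level signals (`02`), pair
distances and line profiles (`03`), the statistical layer (`04`) and the
generator's ground truth (`05`); each prints the numbers it computes and a
line on what they mean.

A thin CLI wraps the same functions for batch use, e.g.

```sh
kinetoquant synth distances --sep-um 1.37 --n 50 --seed 1 --out scenes/
kinetoquant spots --config cfg.yaml --images scenes/ --out spots.csv
kinetoquant stats --in cells.csv --test kruskal-dunn --comparisons "ctrl:icp" --out stats.csv
```

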