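# Methods

## Densitometric model

A Feulgen-stained nucleus absorbs light in proportion to its DNA content.
With blank-field intensity `white_level` and pixel intensity `p`, the
transmittance is `T = p / white_level` and the per-pixel optical density is
`OD = −10·log10(T)` (decadic OD on the conventional ×10 densitometry
scale). The integrated optical density `IOD = Σ OD` over a nucleus's pixel
set is then proportional to total chromophore, hence total DNA, under
three assumptions: stoichiometric staining, flat illumination (a single
scalar `white_level` per image, no shading-field model), and negligible
glare/scatter. No calibration to picograms is attempted — all downstream
quantities are ratios.

`white_level` policies: `max` (bit-depth maximum, the default — appropriate
for blank-corrected scans), `background` (modal pixel intensity of the
image; slides are mostly clear background, so the histogram mode estimates
the blank), or an explicit number. Dark pixels are clamped at
`epsilon·white_level` (default `epsilon = 1e-4`, capping OD at 40 per
pixel) to keep the logarithm finite. Delineations below `min_area = 10`
pixels are rejected as degenerate.

## Geometry

Pixel centers sit at integer (row, col); polygons are closed (x = col,
y = row) vertex lists; a pixel belongs to a polygon iff its center is
inside under the even–odd rule, implemented as deterministic vectorized
ray casting (half-open edge rule, so centers exactly on an edge resolve
consistently). Simulator-exported polygons trace mask boundaries along
pixel corners (half-integer coordinates), which makes polygon and
label-mask representations of the same nucleus rasterize identically.
Nuclei must be pairwise non-overlapping — a shared pixel would credit its
OD to two cells; overlap is an error by default, downgradeable to a
warning for tolerating slips in hand-exported ROI files.

## DNA index and ploidy calls

The modal IOD of the lymphocyte controls is the diploid reference. "Modal"
is made operational as: bin the control IODs into uniform bins (default
width 5% of the median control IOD), take the fullest bin (ties toward the
lower bin), and return the **median of the IODs inside that bin**. The
in-bin median rather than the bin center keeps the estimate
scale-equivariant and exact for tightly clustered controls (identical
controls return their common value verbatim), which in turn makes the
normalization identity exact: a cell whose IOD equals the modal control
IOD gets DI exactly 1.

DI histograms use half-open bins `[lo, hi)` of width 0.05 DI units with
*centers* on round DI values (…, 0.95, 1.00, 1.05, …), following the
flow-cytometry convention of centering the 2N peak on a channel; a value
exactly on an interior edge joins the upper bin. 0.05 resolves 2N from 4N
(20 bins apart) while keeping several cells per bin at 150–200 cells per
sample. The peak DI is the center of the fullest bin, ties toward the
lower DI (conservative toward diploid). Classification: peak ≤ 1.1 →
diploid; 1.1 < peak ≤ 1.40 → mild aneuploidy; above → moderate. The 1.1
boundary is strict. The moderate cutoff is not pinned by published data —
any value between the reported mild-labelled group mean (1.22) and the
moderate-labelled one (1.46) is consistent — so 1.40 is the default and it
is configurable.

## Group statistics

Groups are summarized over per-sample peak DIs: n, mean, sample SD (n−1),
range, and the fraction of samples whose peak DI exceeds 1.1. Pairwise
comparisons use the unpaired t-test from summary statistics — pooled
variance by default (the classical reading of "unpaired t-test"), Welch
with Satterthwaite df as an option — with a one-tailed alternative that
the condition later in the progression order (NCT, L-HP, L-SA, TA, AC)
has the greater mean DI. Significance is α = 0.05 per test with no
multiple-testing correction, matching the original analysis design. Full
precision is carried internally; the rendered matrix rounds to two
decimals. Note an ambiguity inherited from the source tables: the printed
SDs are described per cell population but the tests behave sample-level;
this package computes per-sample SDs (group n = number of samples), the
reading consistent with the printed ranges and fraction denominators.

## Synthetic slides

The simulator is the validation instrument: it renders what the
densitometry model assumes, plus the nuisances the pipeline must tolerate.
Each nucleus is an ellipse (controls 4–6 px radius, epithelial 6–9 px at
the default 512×512, 16-bit geometry) with a radial-dome absorbance
profile `1 − ρ²`, optionally modulated by multiplicative chromatin texture
(sd 15%, clipped positive), renormalized so its discrete sum equals
exactly `absorbance_per_2N × DNA multiple` (default `absorbance_per_2N` =
20, keeping even ~4N nuclei far above the OD clamp floor). Transmitted
intensity is `background_level · white · 10^(−a)` plus additive Gaussian
noise (default sd 1% of white), clipped and quantized to the bit depth.
Placement is dart-throwing with bounded retries under a bounding-circle
separation margin, so nuclei — and their exported boundary polygons —
never overlap. All randomness descends from one integer seed;
reproducibility is bit-exact.

Per-nucleus DNA multiples: controls ~ Normal(1, cv = 5%); the epithelial
compartment is a mixture of populations, by default 92% at the target
multiple and an 8% G2/4N shoulder at twice the target. The default cohort
design mirrors a five-arm colonic study — arm sizes 10 (NCT), 9 (L-HP),
12 (L-SA), 8 (TA), 10 (AC); per-sample target peak DIs drawn from normals
truncated to each arm's reported range, e.g. AC ~ N(1.46, 0.27) on
[1.20, 2.04], with the widest per-cell spread in the AC arm — and 150–200
epithelial cells plus 30 controls per sample.

What the simulator does *not* emulate: tissue architecture, serration
morphology, overlapping or clumped chromatin between cells, stain fading,
shading gradients, and focus blur. Passing tests therefore demonstrate
correctness of the measurement and inference chain under the stated
optical model, not robustness to histological artifacts.

## Numerical choices and problem sizes

Zero/saturated pixels: intensity clipped to [0, white] before
quantization; OD clamped via `epsilon`. Mode/peak ties always break toward
the lower bin. Histogram bin assignment uses floor arithmetic on
`value/width`, immune to edge jitter except at exactly representable
edges, where the half-open rule decides. The t tail uses `scipy.stats.t`;
tests cross-check it against direct quadrature of the t density to 1e-6
and an exhaustive permutation test.

With zero noise and texture the measured IOD matches 10× the true
absorbance to <1% at 16-bit depth (quantization is the only error
source); with default noise, per-sample peak DI of an all-2N sample lands
within one histogram bin of 1.0. Test-suite simulations use reduced
scenes (256–384 px, 10–30 controls, 20–160 epithelial cells, arms of 2–5
samples) chosen to exercise every code path while keeping the suite fast;
the full default cohort (49 samples, ~190 nuclei each) is available via
`aic simulate` and runs in a few minutes.

## Known limitations

- No automatic segmentation: delineation quality is the operator's
  responsibility, and the nonoverlap check is the only safeguard.
- Flat-field assumption: a shading gradient across a slide biases IOD
  regionally; use the `background` white-level policy per image and keep
  controls spatially interspersed to mitigate.
- The modal-IOD estimate inherits histogram-mode jitter of roughly half a
  bin (≈2.5% of the reference by default) at 30 controls; this propagates
  multiplicatively into every DI on the sample.
- Peak DI is quantized to the DI bin width (0.05), so group means move in
  0.05/n steps.
- ImageJ `.roi`/`.zip` import is not implemented; convert to the JSON
  polygon schema or a label mask.
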