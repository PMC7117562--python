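# aicyto

Automated imaging cytometry (AIC) for DNA-ploidy assessment of
Feulgen-stained tissue sections. Given a brightfield slide image and
operator-delineated nucleus outlines, `aicyto` measures each nucleus's
integrated optical density, normalizes epithelial cells to DNA indices
against lymphocyte internal controls, builds per-sample DI histograms,
classifies aneuploidy, and compares condition groups statistically. A
synthetic slide simulator with exact Beer–Lambert ground truth makes every
stage testable without any slide scans.

It is written for pathology-imaging researchers who quantify nuclear DNA
content *in situ* — e.g. grading colonic polyps by chromosomal-instability
burden — and who want a transparent, scriptable alternative to commercial
image-cytometry systems.

## Method

The Feulgen stain binds DNA stoichiometrically, so under Beer–Lambert
absorption a nucleus's **integrated optical density**

```
IOD = Σ_pixels −10·log10(p / white_level)
```

is proportional to its total DNA content (`p` is the pixel intensity,
`white_level` the blank-field intensity; the ×10 factor is densitometry
convention and cancels in every ratio).

Per sample, the modal IOD of ≥30 delineated lymphocytes defines the
internal diploid (2N) reference and is assigned **DNA index** DI = 1; each
of the 150–200 epithelial nuclei gets `DI = IOD / modal_control_IOD`, so
DI 2 means tetraploid. A histogram of cells vs DI (bin width 0.05, bins
centered on round DI values) is built and the **peak DI** — the center of
the fullest bin — represents the sample. A sample is **aneuploid** when
its peak DI exceeds 1.1 (strict; graded *mild*, or *moderate* above a
configurable second cutoff, default 1.40).

Groups of samples are summarized (n, mean, SD, range of peak DI, aneuploid
fraction) and compared pairwise with one-tailed unpaired t-tests
(pooled-variance by default, Welch optional), the alternative following
the neoplastic-progression order NCT → L-HP → L-SA → TA → AC, α = 0.05.

The simulator renders non-overlapping elliptical nuclei whose per-pixel
absorbance fields integrate exactly to `absorbance_per_2N × DNA multiple`,
then applies Beer–Lambert transmission, Gaussian intensity noise and
quantization — so measured IOD has a known ground truth.

## Worked example

```python
import warnings
from aicyto import SceneSpec, render_scene, measure_sample, analyze_sample

spec = SceneSpec(seed=11)             # 30 controls + 160 epithelial, 16-bit
plane, rois, truth = render_scene(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # protocol-count advisories
    ms = measure_sample(plane, rois)
res = analyze_sample(ms, sample_id="demo")
print(round(res.modal_control_iod, 2), res.peak_di, res.ploidy_class)
```

prints

```
195.31 1.05 diploid
```

— the lymphocyte modal IOD is ≈195 OD·px (ground truth 200 for a 2N
nucleus with the default total absorbance 20 and the ×10 OD scale; the
mode of 30 noisy controls lands within a few percent), the epithelial
histogram peaks at DI 1.05, and the sample is called diploid since
1.05 ≤ 1.1.

The same flow from a shell, on real or simulated files:

```
aic simulate --seed 1 --out-dir cohort/          # 49 samples, 5 conditions
aic run --layout cohort/layout.csv --out-dir report/
```

`report/group_summary.csv` then holds one row per condition (mean/SD/range
of peak DI, aneuploid fraction) and `report/ttest_matrix.csv` the
upper-triangular one-tailed p-value matrix; every output embeds the
configuration hash, and identical inputs reproduce byte-identical files.

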