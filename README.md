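# zctexture

Quantification of receptor-clustering immunofluorescence images: the
zero-crossing (ZC) texture score, ImageJ-style per-cell masking and
intensity measurements, and multi-channel ridge-profile analysis — with a
ground-truthed synthetic scene generator so the whole pipeline is testable
without microscope data.

## The problem

Collagen-binding receptor tyrosine kinases such as DDR1 reorganise on the
cell surface after ligand addition: a fine punctate stain becomes connected
and linear within 5–10 minutes, then compacts into coarse dense aggregates
by 45–60 minutes, and only the dense aggregates carry phosphorylated
receptor.  Quantifying that progression needs an unbiased texture statistic
(how fine or coarse is the stain?), per-cell intensity measurements with
their normalization schemes, and — at super-resolution — width and
"double-wall" analysis of the aggregated structures, whose receptor stain
splits into two parallel ridges with ligand and phospho-receptor signal
filling the gap.

## The ZC score

For a texture patch P the image is locally average-subtracted (window
w ≈ 10 μm, renormalised at patch edges) to give a reference image R with
zero in-patch mean.  Random lines ℓ₁…ℓₙ (uniform anchor, uniform angle,
n = 2000 by default) are drawn across P and R is sampled along each at
1-px steps:

    ZC = (1/n) · Σᵢ  crossings(R | ℓᵢ) / length(ℓᵢ)     [crossings / μm]

Higher ZC = finer texture; lower = coarser, denser signal.  The score is
exactly invariant to rescaling the intensities.  It has closed-form
anchors: a sinusoidal grating of period P px gives 4/(πP) crossings per px
over uniform angles, and an isotropic Gaussian random field with
correlation length ℓ gives 1/(πℓ) (Rice's formula); both are enforced in
the test suite.

## Worked example

```python
from zctexture import SceneConfig, generate_scene, make_cell_mask, \
    segment_texture_patches, zc_score

# a synthetic 12.8 um cell with a linear-cluster texture (0.3 um ridges)
scene = generate_scene(SceneConfig(texture_class="linear_cidc",
                                   char_length_um=0.3, density=0.5, seed=3))
ddr1 = scene.channels["ddr1"]

mask = make_cell_mask(ddr1)                      # threshold + 2x [dilate/fill/erode]
patches = segment_texture_patches(ddr1, mask)    # 1-4 texture patches
res = zc_score(ddr1, patches[0], n_lines=2000, seed=7)
print(f"{len(patches)} patch(es); ZC = {res.zc_score:.3f} crossings/um")
```

prints

```
1 patch(es); ZC = 1.205 crossings/um
```

i.e. the whole cell is one clean texture patch and a random line crosses
the zero level of the background-subtracted stain about 1.2 times per μm —
between the fine punctate regime (≈ 2.1 under the same settings) and the
coarse aggregate regime (≈ 0.63), which is exactly the ordering a
stimulation timecourse produces.  The same objects drive the timecourse
pipeline:

```python
from zctexture.io import AnalysisConfig
from zctexture.pipeline import run_timecourse_analysis

tables = run_timecourse_analysis(AnalysisConfig(seed=2, out_dir="results"))
print(tables["summary"][["time_min", "zc_mean", "py_norm_mean"]].round(4))
```

```
   time_min  zc_mean  py_norm_mean
0       0.0   2.1134        0.0000
1      10.0   1.1373       24.8528
2      60.0   0.6347      100.0000
```

— the texture score falls monotonically while the anchor-normalised
phospho signal rises to 100 A.U.

A `zctex` command-line tool wraps the same functions
(`simulate`, `segment`, `zc-score`, `quantify`, `profile`, `densitometry`,
`compare`, `run`); every subcommand reads/writes TIFF + CSV/JSON.

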