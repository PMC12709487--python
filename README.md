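# tissuemetrics

Quantitative texture characterization of brightfield tissue-microscopy
images, for researchers studying structural disorder in histology — e.g.
distinguishing regular from disrupted tissue architecture in tumor
specimens. In transmission imaging the recorded intensity tracks local
mass density (denser tissue refracts and absorbs more), so the spatial
statistics of the intensity raster carry the tissue's structural
signature. The package measures that signature four complementary ways:

1. **Sub-box fractal-dimension maps.** Each 512×512 grayscale image is
   thresholded and divided into 32×32 sub-boxes; within each, the
   box-counting dimension is the slope of ln N(ε) vs ln(1/ε), where N(ε)
   is the number of occupied ε-cells. One image yields a 16×16 map of
   256 local D_f values.
2. **Distribution transforms.** The D_f distribution is sharpened by the
   log map ln D_f and the functional transform
   D_tf = D_f / (D_f^max − D_f), which diverges at the maximum dimension
   recorded across the analyzed set and stretches the right tail where
   disordered tissue concentrates. Each distribution is summarized by a
   70-bin histogram, a polynomial smoothing, and a Gaussian fit with an
   R²-style goodness score.
3. **Chhabra–Jensen multifractal spectrum.** Box intensity masses
   P_i(ε) are reweighted by moment order q, μ_i = P_i^q / Σ P_j^q, and
   α(q), f(α(q)) follow as cross-scale regression slopes of
   Σ μ_i ln P_i and Σ μ_i ln μ_i against ln ε. Spectrum width, peak and
   asymmetry quantify textural heterogeneity.
4. **Inverse participation ratio (IPR).** Per block, the relative
   intensity fluctuation ε_i = (I_i − I₀)/I₀ is the on-site potential of
   an Anderson tight-binding Hamiltonian
   H = Σ ε_i |i⟩⟨i| + t Σ_⟨ij⟩ |i⟩⟨j|; the mean Σ|ψ|⁴ over all L²
   eigenstates (area-normalized to L²·Σψ⁴) measures eigenfunction
   localization, which grows with the structural disorder parameter
   L_d = ⟨dn⟩·l_c (fluctuation strength × correlation length).

Because comparable public image cohorts are unavailable, the package
ships a first-class synthetic module with analytically known ground
truth: Sierpinski carpets (D_f = ln8/ln3), randomized multiplicative
cascades (exact spectrum τ(q) = −log₂ Σ p_i^q), correlated Gaussian
disorder fields with prescribed ⟨dn⟩ and l_c, and labeled two-cohort
"control"/"disease" studies built from them.

## Worked example

```python
import numpy as np
from tissuemetrics import boxcount, mfa, report, synth

# deterministic oracle: the level-5 Sierpinski carpet
carpet = synth.sierpinski_carpet(5)
curve = boxcount.box_count(carpet.pixels, [3, 9, 27, 81])
print(round(boxcount.fit_dimension(curve), 4))   # 1.8928  (= ln8/ln3)

# a synthetic 5+5 image study at 256 px
spec = synth.CohortSpec(n_images=5, control=synth.CONTROL_PRESET,
                        disease=synth.DISEASE_PRESET, side=256,
                        master_seed=1)
cfg = report.RunConfig(cohort_spec=spec, block_side=32, ipr_block_side=16)
bundle = report.run_full_analysis(cfg)
cols = ["metric", "control_mean", "disease_mean", "mean_pct_difference"]
print(bundle.comparisons[cols].round(4).to_string(index=False))
```

prints

```
1.8928
       metric  control_mean  disease_mean  mean_pct_difference
           Df        1.7144        1.8197               6.1415
         lnDf        0.5257        0.5921              12.6341
        lnDtf        2.4026        3.3342              38.7787
f_alpha_width        0.1609        0.4285             166.3629
          IPR        2.6232        2.8225               7.5968
```

The disease arm (stronger intensity fluctuations, longer correlation
length, more heterogeneous cascade weights) shows a higher mean fractal
dimension, and the percentage contrast grows monotonically along
D_f → ln D_f → ln D_tf — the transforms amplify group separation. Its
f(α) spectrum is ~2.7× wider and its IPR mean and spread are elevated,
each metric reading the same structural disorder a different way.

A thin CLI mirrors the library: `tc simulate`, `tc prep`, `tc fractal`,
`tc mfa`, `tc ipr`, `tc run` (see `tc --help`).

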