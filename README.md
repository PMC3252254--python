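# caudatecut

Seeded graph-cut segmentation of small, low-contrast brain structures —
built around the caudate nucleus in T1 MRI — with a synthetic phantom
generator, the standard volumetric evaluation metrics, and the group-level
volume analysis used in neurodevelopmental morphometry (e.g. the
right-lateralized caudate volume reduction reported in pediatric ADHD).

The caudate is hard to segment automatically: it is small, its intensity is
non-uniform, and its boundary with surrounding gray matter is weakly
contrasted. Atlas-based pipelines localize it well but inherit the atlas's
shape errors. This package refines an approximate **prior mask** (from any
atlas tool, or from the built-in phantom generator) by exact energy
minimization.

## The model

A binary labeling `L` of a slice (cau / back) is scored by

```
E(L) = Σ_p U_p(L_p)  +  δ · Σ_{p,q} B_{p,q} · [L_p ≠ L_q]
```

and minimized exactly by min-cut/max-flow on a two-terminal pixel graph,
subject to hard seed constraints: caudate seeds `C = Erode_ke(R0)` and
background seeds `B = P \ Dilate_kd(R0)` derived from the prior `R0`.

* **Unary term** `U = UU + SU`: `UU_p = −ln P_u(L_p | I_p)` from the
  graylevel histogram of the caudate seeds (background as the complement),
  plus `SU_p = −ln P_s(L_p)` from a calibrated linear SVM over a
  **correlogram descriptor** — the `n(n−1)/2` signed mean-graylevel
  differences between all pairs of the `n = c·r` ring/sector bins around
  the pixel, which captures contextual structures such as the adjacent
  lateral ventricle.
* **Boundary term** `B_{p,q} = (1−J̄_{pq}) · (α N_{p,q} + (1−α) O_{p,q})`:
  an intensity-similarity Gaussian `N`, an orientation-similarity Gaussian
  `O` on the angle between the Hessian minimum-eigenvalue directions (at a
  per-pixel scale selected by local window-entropy maximization), and a
  multi-scale Canny **edgeness map** `J` that releases regularization where
  the image itself votes for a boundary. `σ` and `β` adapt to each slice.

Evaluation follows the CAUSE07 conventions: SI (Dice, %), VO (Jaccard, %),
VD (relative absolute volume difference, %), and the pooled symmetric
surface distances AD / RMSD / MD in millimeters.

## Worked example

`examples/01_segment_phantom.py` builds a six-subject phantom cohort,
trains the correlogram classifier on five subjects and segments the sixth
subject's right caudate from its jittered prior:

```
$ python examples/01_segment_phantom.py
graph cut : SI  77.71 %  VO  63.55 %  MD 4.90 mm
prior     : SI  69.92 %  VO  53.75 %  MD 6.00 mm
SI/VO near 100 is better; MD (max surface distance) near 0 is better.
```

The cut recovers about 8 SI points over the atlas-like prior it was seeded
from. `examples/02_energy_components.py` prints the pieces of the energy on
one slice (seed counts, unary costs, adaptive σ/β, edgeness) together with
the exact minimum found; `examples/03_group_volume_analysis.py` reproduces
the lateralized group analysis:

```
$ python examples/03_group_volume_analysis.py
  side   M ctrl   M case       d      t        p  decision
 right   4799.2   4291.9   507.3   4.05   0.0001  reject H0
  left   4798.8   4628.9   169.8   1.34   0.1835  accept H0
```

A thin CLI mirrors the workflow for shell use:

```
caudatecut phantom  --out cohort/ --n-control 8 --n-case 8 --seed 0
caudatecut segment  --volume sub.nii.gz --prior prior.nii.gz --out mask.nii.gz
caudatecut evaluate --pred mask.nii.gz --gt gt.nii.gz --out report.csv
caudatecut cohort   --out run/ --deficit 0.10 --seed 0
```

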