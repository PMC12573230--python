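# imsrpca

Low-rank + sparse + dense matrix decompositions for imaging mass
spectrometry (IMS).

An IMS experiment records a full mass spectrum at every pixel of a tissue
section; after peak picking the data set is a matrix **A** with *m* rows
(pixels) and *n* columns (m/z peaks), and *m* ≫ *n*. Classical
dimensionality reduction replaces **A** by a low-rank approximation, but
tissue often contains small, high-intensity structures that are spatially
sparse and get smeared into the low-rank basis (or inflate its rank) by
plain PCA. This package decomposes

```
A = B + C + D,    B = Y Zᵀ  (rank r ≪ min(m, n))
```

into a low-rank term **B** (correlated anatomical structure), a sparse
residual term **C** (small high-intensity structures, isolated peaks) and
a dense residual term **D** (entry-wise noise), using three methods:

* **PCA** — `min ‖A − B‖  s.t.  rank(B) ≤ r` (truncated SVD; `D = A − B`,
  no C);
* **PCP** (principal component pursuit) —
  `min ‖B‖* + λ‖C‖₁  s.t.  A = B + C` (no D), solved by an inexact
  augmented-Lagrangian iteration of singular-value and soft thresholding;
* **SPCP** (stable PCP) —
  `min ‖B‖* + θ‖C‖₁  s.t.  ‖A − B − C‖_F ≤ δ` (`D = A − B − C`), solved
  by the same splitting with a Frobenius-ball projection for the dense
  residual.

Around the solvers the package provides: dimension-free parameter
multipliers and sweep grids (λ, θ ↦ mult/√max(m,n); δ from a noise-ball
σ-multiplier), comparison metrics (average subspace overlap — the mean of
the singular values of `U₁ᵀU₂` — and percentage/sum/mean of negative
entries, a physicality heuristic for non-negative ion counts), per-term
energies and intensity histograms, refolding of matrix columns into ion
images, imzML/HDF5/CSV I/O, trimmed TIC normalization, a synthetic
IMS-like data generator with known ground truth, and a CLI.

## Worked example

```python
import numpy as np
from imsrpca import (gen_synthetic_ims, pca_fit, spcp_fit,
                     negativity_stats, subspace_overlap)
from imsrpca.parameters import theta_from_multiplier, delta_from_multiplier

x, truth = gen_synthetic_ims(seed=0)          # 64x64 pixels, 100 peaks
m, n = x.values.shape
theta = theta_from_multiplier(1.0, m, n)
delta = delta_from_multiplier(1e-3, m, n, float(np.linalg.norm(x.values)))
d = spcp_fit(x.values, theta, delta)
print(f"rank(B) = {d.rank_r}, iterations = {d.diagnostics['iterations']}, "
      f"converged = {d.diagnostics['converged']}")
frac = np.sum(d.C[truth.support] ** 2) / np.sum(truth.S0 ** 2)
print(f"planted sparse energy captured by C: {frac:.3f}")
d_pca = pca_fit(x.values, d.rank_r)
print(f"pct negative entries: B_SPCP = "
      f"{negativity_stats(d.B).pct_negative:.4f}%, "
      f"B_PCA = {negativity_stats(d_pca.B).pct_negative:.4f}%")
print(f"column-subspace overlap SPCP vs PCA: "
      f"{subspace_overlap(d.U, d_pca.U):.3f}")
```

prints

```
rank(B) = 4, iterations = 34, converged = True
planted sparse energy captured by C: 0.992
pct negative entries: B_SPCP = 0.0000%, B_PCA = 0.0583%
column-subspace overlap SPCP vs PCA: 0.999
```

The cube is built from 4 smooth anatomical layers plus 10 small
high-intensity blobs plus noise. SPCP recovers exactly the 4-layer rank,
routes 99% of the planted blob energy into the sparse term C, and its
low-rank term contains essentially no (non-physical) negative
intensities, while PCA at the same rank must absorb the blobs and noise
into B and D and picks up negative entries doing so. The two methods
still agree closely on the dominant spatial basis (overlap ≈ 1).

The same workflow is available from the shell:

```sh
imsrpca simulate --height 64 --width 64 --n-peaks 100 --seed 0 --output cube.h5
imsrpca decompose --method spcp --theta-mult 1.0 --sigma-mult 1e-3 \
    --input cube.h5 --output dec.h5
imsrpca metrics --decomposition dec.h5
imsrpca quartet --method spcp --input cube.h5 --mz-index 10 --output quartet.png
```

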