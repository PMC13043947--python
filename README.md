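# stainbench

Benchmarking of classical H&E stain-normalization methods, with the
selection procedures, evaluation metrics and a synthetic multi-laboratory
slide generator needed to run the whole comparison at desk scale.

Tissue sections cut from one block but stained in different laboratories
vary drastically in color — stain formulation, protocol and scanner all
shift the distribution while the morphology stays fixed.  That variation
degrades both pathologist reading and AI-based analysis, and *stain
normalization* — mapping a source image's colors onto a reference image's
while preserving structure — is the standard computational remedy.  This
package is for image-analysis researchers who want to benchmark
normalization methods the way multi-center staining studies do, without
needing a multi-center dataset to start.

## What is inside

- **`stainbench.color`** — RGB ↔ optical density (Beer–Lambert,
  `od = −log₁₀(I/i₀)`) and RGB ↔ Ruderman lαβ (decorrelated log-LMS),
  plus PNG/TIFF I/O.
- **`stainbench.normalize`** — the four classical methods, each mapping
  `(source, reference) → normalized image` on the whole image at once:
  - *histogram matching*: per-channel monotone quantile mapping;
  - *Reinhard*: per-channel mean/std matching in lαβ;
  - *Macenko*: stain deconvolution; stain vectors at the extreme
    percentile angles of the OD cloud's top-2 SVD plane, per-stain
    99th-percentile concentration rescaling,
    `od = W_ref · diag(s) · C_src`;
  - *Vahadane*: stain basis and density from sparse non-negative matrix
    factorization, `min ‖V − WH‖²_F + λΣH`, density rescaled and
    recombined with the reference basis.
- **`stainbench.select`** — reference selection (image whose red/blue
  mean-intensity ratio is closest to 1) and representative selection
  (lαβ-histogram features → 2-component PCA → seeded k-means → member
  nearest each centroid, with a WCSS elbow diagnostic).
- **`stainbench.metrics`** — histogram intersection, Pearson correlation,
  Euclidean distance and Jensen–Shannon divergence on lαβ channel
  histograms; SSIM against the original; Fréchet distance
  `‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½)` on tile-level feature clouds with a
  pluggable, download-free default extractor.
- **`stainbench.synth`** — one shared tissue morphology rendered by N
  virtual laboratories with jittered stain matrices, log-normal over-/
  under-staining, smooth unevenness and background tint; full ground
  truth retained.
- **`stainbench.bench`** — end-to-end orchestration: select reference,
  normalize everything with every method, evaluate, aggregate to
  per-method mean/std tables and R/B-ratio convergence plots.

## Worked example

```python
import numpy as np
from stainbench import make_panel, select_reference
from stainbench.bench import BenchConfig, run_benchmark

panel = make_panel(n_labs=6, height=256, width=256, seed=11)
idx, ratios = select_reference(panel.images, panel.ids)
print("reference:", panel.ids[idx])
print({r.sample_id: round(r.ratio, 3) for r in ratios})

report = run_benchmark(dict(zip(panel.ids, panel.images)),
                       config=BenchConfig(tile_size=64, seed=11))
print(report.aggregates[[("intersection", "mean"), ("js", "mean"),
                         ("ssim", "mean")]].round(3))
```

prints

```
reference: lab04
{'lab00': 1.299, 'lab01': 1.351, 'lab02': 1.117, 'lab03': 1.187,
 'lab04': 1.052, 'lab05': 1.179}
          intersection     js   ssim
                  mean   mean   mean
method
histmatch        0.693  0.192  0.961
macenko          0.864  0.054  0.910
reinhard         0.691  0.172  0.912
vahadane         0.817  0.072  0.909
```

`lab04` is chosen as the reference because its red-to-blue ratio (1.052)
is the closest to the balanced value 1.  After normalization every method
pulls the panel's colors toward the reference: histogram intersection
with the reference rises (1 would be identical histograms), the
Jensen–Shannon divergence falls (0 would be identical), and SSIM against
the originals stays above 0.9, i.e. tissue structure is preserved.  On
this panel the deconvolution methods transfer color most faithfully while
histogram matching preserves structure best — which methods win depends
on the panel's variation structure.  The R/B convergence diagnostic shows
the panel-wide effect: mean |R/B − 1| drops from 0.198 before
normalization to 0.04–0.05 for every method.

The same pipeline is available from the shell:

```sh
stainbench simulate --out panel --n-labs 20 --size 512 --seed 17
stainbench benchmark --input-dir panel --out results --seed 17
```

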