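# sparsect

Sparse-view CT reconstruction with a learned artifact score as a Bayesian
penalty.

## The problem

Cutting the number of projection views in CT lowers dose, but filtered
backprojection (FBP) from few views produces severe streak (angular
aliasing) artifacts: the system `A X = Y` is underdetermined, and the
missing information must come from priors.  The classical prior is the
total-variation (TV) norm.  This package implements, tests, and studies a
complementary learned prior: a small convolutional classifier is trained
to tell "good" full-view FBP reconstructions (label 0) from "bad"
few-view ones (label 1); its sigmoid output layer is then discarded, and
the remaining real-valued logit `CNN(X) ∈ (−∞, ∞)` — large for streaked
images, small for clean ones — is penalised inside the variational
objective

```
F(X) = α₁‖AX − Y‖² + α₂·CNN(X) + α₃·TV(X)
```

minimised by steepest descent with a backtracking line search.  It is
aimed at people experimenting with learned regularisers for tomographic
inverse problems who want a complete, dependency-light, reproducible
pipeline: parallel-beam projector with an exact adjoint, FBP, phantom
corpus generator, the classifier (pure numpy, 7,580 parameters), and the
iterative solver with per-iteration diagnostics.

Because no patient data ships with the package, a synthetic-phantom
module generates the training corpus: random ellipse phantoms rendered
inside an elliptical body, each reconstructed once from 360 views (label
0) and once from 45 views over 180° (label 1).

## Worked example

```python
import numpy as np
from sparsect import (Geometry, PhantomConfig, CnnConfig, TrainConfig,
                      ReconConfig, TvConfig, build_corpus, build_model,
                      train_classifier, generate_phantom, forward_project,
                      fbp, cnn_score, reconstruct, inscribed_circle_mask)

few  = Geometry(n_views=45,  n_bins=64, image_size=64)   # incomplete scan
full = few.with_views(360)                               # complete scan

# 1. corpus: 400 phantoms, each reconstructed from both scans
corpus = build_corpus(PhantomConfig(image_size=64, seed=42), 400, few, full)

# 2. train the good/bad classifier, then drop the sigmoid
model = build_model(CnnConfig(input_size=64), seed=7)
model, report = train_classifier(
    model, corpus,
    TrainConfig(epochs=30, learning_rate=3e-3, batch_size=16, seed=7))
model.to_score_mode()

# 3. reconstruct a fresh phantom from 45 views
phantom = generate_phantom(PhantomConfig(image_size=64, seed=2024), 0)
y = forward_project(phantom, few)
naive = fbp(y, few)
rc = ReconConfig(alpha1=1.0, alpha2=5.0, alpha3=1e-3, n_iter=200,
                 step_size=1e-4)
x, trace = reconstruct(y, few, model, rc, TvConfig(epsilon=1e-3))

mask = inscribed_circle_mask(few)
rmse = lambda a: float(np.sqrt(np.mean((a - phantom)[mask] ** 2)))
print(f"final validation accuracy  {report.val_acc[-1]:.2f}")
print(f"FBP:   rmse {rmse(naive):.4f}   CNN score {cnn_score(model, naive):+.2f}")
print(f"recon: rmse {rmse(x):.4f}   CNN score {trace.cnn_score[-1]:+.2f}"
      f"  (started at {trace.cnn_score[0]:+.2f})")
```

Output (takes a few minutes; the training step dominates):

```
final validation accuracy  0.99
FBP:   rmse 0.0722   CNN score +5.26
recon: rmse 0.0468   CNN score +1.70  (started at +5.26)
```

Read: the classifier separates the two reconstruction classes almost
perfectly; the 45-view FBP image scores high (artifact-like); iterative
reconstruction with the CNN penalty cuts the in-circle RMSE by ~35%
relative to FBP and drives the artifact score down — the per-iteration
`trace` records F, its three components, and the accepted step at every
iteration.  Setting `alpha2=0` in the same run isolates the CNN term's
contribution.

The same pipeline is available from a shell:

```
sparsect phantom -n 400 --seed 1 --out corpus.h5
sparsect train corpus.h5 --epochs 30 --out weights.h5
sparsect reconstruct sino.h5 weights.h5 --out recon.tif
```

Every command writes a JSON sidecar with its fully resolved
configuration.

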