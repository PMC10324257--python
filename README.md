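# ocusiam

Siamese metric learning with channel/spatial attention and a k-nearest-neighbor
readout for two-class ocular ultrasound B-scan classification.

## The problem

On fundus ultrasound, two common posterior-segment findings look superficially
similar but differ in lesion morphology: **vitreous opacities (VO)** echo as
*discrete* bright spots floating in the vitreous, while a **posterior vitreous
detachment (PVD)** echoes as a *continuous* bright membrane arcing above the
retina. Labeled clinical datasets for this task are small (a few hundred
images), which rules out training a large classifier head from scratch.
Metric learning sidesteps that: a shared-weight convolutional branch is trained
on *pairs* of images so that same-class scans embed close together and
different-class scans embed far apart, and classification reduces to a
nearest-neighbor vote in the learned embedding space — a regime that works
with far fewer labels.

## The model

One branch network `f_θ` (VGG16-, AlexNet-, ResNet18-style, or a desk-scale
"tiny" variant) maps a preprocessed scan to an embedding. The final feature
map is refined by a sequential channel + spatial attention block:

    M_c(F) = σ(MLP(AvgPool(F)) + MLP(MaxPool(F)))            ∈ ℝ^{C×1×1}
    M_s(F) = σ(f^{k×k}([AvgPool_c(F); MaxPool_c(F)]))        ∈ ℝ^{1×H×W}
    F″ = M_s(M_c(F) ⊙ F) ⊙ (M_c(F) ⊙ F)

Training minimizes the contrastive loss over N image pairs with match label
y (1 = same class) and embedding distance d = ‖f_θ(x₁) − f_θ(x₂)‖₂:

    L = 1/(2N) Σ [ y·d² + (1−y)·max(margin − d, 0)² ]

At inference, every training image is embedded once into a labeled *gallery*;
a query is classified by majority vote among its k = 2 nearest gallery
entries (Euclidean), with vote ties resolved by the single nearest neighbor.

Preprocessing is crop → resize to 224×224 (64×64 in the desk profile) →
per-channel normalization `(x − 0.5)/0.5`. Default training hyperparameters:
Adam, learning rate 1e-5, batch size 50 pairs, 50 epochs, margin 1.0.

The neural-network core (reverse-mode autodiff, conv/pool/batch-norm layers,
Adam) is implemented in NumPy inside `ocusiam.nn`; gradient correctness is
verified against finite differences in the test suite.

Because clinical B-scan datasets of this kind are not redistributable, the
package ships a synthetic generator (`ocusiam.synthetic`) that renders the
class-defining morphology — discrete bright foci vs a continuous bright arc
on a dark elliptical fundus with speckle — so the whole pipeline is testable
end to end.

## Worked example

```python
from ocusiam import SiameseKNN
from ocusiam.synthetic import SyntheticSpec, LesionParams, generate_dataset

spec = SyntheticSpec(size=128, n_per_class=30, noise_level=0.0, seed=11,
                     lesions=LesionParams(spot_count=3, spot_radius=(4.0, 7.0),
                                          spot_intensity=(0.8, 0.95),
                                          arc_thickness=4.0))
generate_dataset(spec, "data/")

model = SiameseKNN.from_manifest("data/manifest.csv", images_root="data",
                                 train_fraction=2/3, split_seed=0,
                                 **SiameseKNN.desk_profile(0))
res = model.fit(seed=0)
print(res.summary())
```

prints

```
Siamese metric-learning classifier with KNN readout
===================================================
branch architecture : tiny
attention           : both
embedding dim       : 16
training images     : 40
epochs run          : 8
seed                : 0
first-epoch loss    : 0.0671
final-epoch loss    : 0.0024
---------------------------------------------------
test images         : 20
positive class      : PVD
accuracy            : 1.000
precision           : 1.000
recall              : 1.000
F1                  : 1.000
```

The loss falls from 0.067 to 0.002 over eight epochs — the contrastive
objective has pulled same-class embeddings together and pushed the two
classes past the margin — and the KNN readout then classifies every held-out
synthetic scan correctly (on noiseless, well-separated synthetic data this
regime is solvable by construction; it validates the pipeline, not clinical
performance). `res.predict("data/vo_0003.png")` classifies a single image;
`res.save("run/")` writes the checkpoint, gallery, loss history and
provenance.

The same pipeline is scriptable from a shell:

```sh
ocusiam generate --n-per-class 30 --size 128 --noise 0 --seed 11 --out data/
ocusiam train    --manifest data/manifest.csv --images-root data --out run/
ocusiam ablate   --manifest data/manifest.csv --images-root data --out ablation/
ocusiam sweep-k  --manifest data/manifest.csv --images-root data --out sweep/
```

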