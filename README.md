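# octpt — unpaired mutual conversion between OCT scanning presets

Optical coherence tomography platforms trade scanned area against per-image
averaging: the fast **Macular Cube** volume preset averages ~9 B-scans per
tomogram over a wide fundus patch (noisy, plentiful), while the intensive
**Seven Lines** preset averages ~25 B-scans over a narrow strip (clean,
scarce). The visual gap between presets limits dataset pooling for
computer-aided diagnosis. `octpt` implements a fully automatic methodology
for converting B-scans of one preset into the visual style of the other,
in both directions, without paired data:

* a **contrastive unpaired translation GAN**: a residual encoder–decoder
  generator `G = G_dec ∘ G_enc` trained against a patch discriminator with
  the adversarial objective
  `L_GAN = E_y log D(y) + E_x log(1 − D(G(x)))`
  (least-squares variant available and default), regularised by a **patchwise
  noise-contrastive loss**. For encoder layers `l ∈ {0,4,8,12,16}` and
  sampled locations `s`, embedded patches `ẑ_l^s` of the translation are
  pulled toward the same-location patches `z_l^s` of the input and pushed
  from other-location patches `z_l^{S∖s}`:
  `ℓ(q,q⁺,q⁻) = −log[ exp(q·q⁺/τ) / (exp(q·q⁺/τ) + Σ_n exp(q·q_n⁻/τ)) ]`
  with temperature τ = 0.07 — preserving anatomy while restyling speckle;
* **quality-driven checkpoint selection**: generator checkpoints (every 20
  epochs of a 400-epoch schedule at full scale) are ranked by the mean of a
  no-reference quality score over their generated images (ENL, CNR and a
  36-feature natural-scene-statistics score in the BRISQUE family are
  provided); the lowest-scoring checkpoint is selected for the clean-preset
  generator and the highest for the noisy-preset generator;
* an **automatic separability test**: a preset classifier trained on original
  images only (60/20/20 balanced split, early-stopped on validation loss)
  checks whether converted images are classified as their *target* preset;
* a **layered speckle-phantom generator** standing in for clinical data: the
  two presets are simulated from the same tissue-reflectivity model,
  differing only in the number of averaged speckle looks (9 vs 25), so that
  `ENL = mean²/var` of a homogeneous background recovers the look count.

Because no deep-learning framework is assumed, the networks run on a small
NumPy reverse-mode autodiff engine included in the package (`octpt.nn`).

## Worked example

```python
import numpy as np
from octpt import phantom as ph
from octpt.cutgan import CUTModel, TrainingConfig
from octpt import quality as q

# two unpaired synthetic sets: 9-look cube scans and 25-look seven-line scans
rng = np.random.default_rng(0)
make = lambda preset, n: [
    ph.simulate_bscan(ph.make_reflectivity_map(ph.sample_phantom_spec(rng, 64, 64)),
                      preset, seed=i, source_id=f"{preset.name}_{i}")
    for i in range(n)]
cube, seven = make(ph.MACULAR_CUBE, 40), make(ph.SEVEN_LINES, 40)

res = CUTModel(cube, seven, TrainingConfig.desk(seed=0, epochs=3)).fit()
print(res.summary())
converted = res.convert(cube[0])
print(converted.preset, converted.provenance)   # seven_lines synthetic
```

prints (trained for 3 reduced epochs; losses will vary with the seed):

```
Contrastive unpaired translation results
============================================
direction:            macular_cube -> seven_lines
images (src/tgt):     40 / 40
epochs:               3 (decay from 1)
gan mode:             least_squares
generator params:     269185
checkpoints saved:    1 at epochs [3]
final losses:         G_GAN=0.3481  D_real=0.2325  D_fake=0.2093  G=3.1003  NCE=2.8895  NCE_Y=2.6149
seven_lines synthetic
```

`G_GAN`/`D_real`/`D_fake` are the least-squares adversarial terms, `NCE` and
`NCE_Y` the patchwise contrastive terms for source- and target-class images,
and `G` the full generator objective. The whole study — phantom dataset, both
conversion directions, checkpoint selection, conversion, separability — runs
with one call:

```bash
octpt pipeline --out runs/desk --preset desk --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `octpt.phantom` | phantom specs, multi-look speckle simulation, dataset + manifest I/O |
| `octpt.cutgan` | generator/discriminator/projection heads, losses, `CUTModel`/`CUTResults`, conversion |
| `octpt.quality` | ENL, CNR, NSS features and pluggable scorer, score summaries, checkpoint selection |
| `octpt.separability` | balanced splits, preset classifier, accuracy, synthetic separability test |
| `octpt.pipeline` / `octpt.cli` | end-to-end orchestration and the `octpt` command |
| `octpt.nn` | NumPy autodiff engine (conv2d, instance norm, Adam) |

See `docs/methods.md` for the model, parameter and design details.
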