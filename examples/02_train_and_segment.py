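"""Train a small multi-scale residual U-Net and segment held-out scenes.

A deliberately tiny run (64 px scenes, reduced-width network, ~1 minute on
one CPU) that still shows the full loop: compound dice + cross-entropy
loss falling, validation DSC rising, and held-out evaluation of the raw vs
post-processed masks.
"""

import numpy as np

from orgamorph import (
    ModelConfig,
    SimConfig,
    TrainConfig,
    build_model,
    clean_mask,
    dice,
    generate_scene,
    predict_mask,
    train,
)


def make_scenes(n, seed0):
    pairs = []
    for i in range(n):
        cfg = SimConfig(
            height=64,
            width=64,
            n_organoids=2,
            diameter_median_um=50,
            diameter_min_um=35,
            diameter_max_um=60,
            seed=seed0 + i,
        )
        img, gt, _ = generate_scene(cfg)
        pairs.append((img, gt))
    return pairs


train_set = make_scenes(6, 0)
val_set = make_scenes(2, 100)
test_set = make_scenes(4, 200)

model = build_model(ModelConfig(depth=2, base_channels=8, seed=0))
cfg = TrainConfig(crop=64, batch=4, epochs=40, seed=0)
model, hist = train(model, train_set, val_set, cfg)

print("epoch  loss_total  val_DSC")
for e in range(0, cfg.epochs, 8):
    print(f"{e:>5}  {hist.loss_total[e]:>10.3f}  {hist.val_dsc[e]:>7.3f}")
print(f"best epoch: {hist.best_epoch} (val DSC {max(hist.val_dsc):.3f})")

raw = []
post = []
for img, gt in test_set:
    _, pred = predict_mask(model, img)
    raw.append(dice(pred, gt))
    post.append(dice(clean_mask(pred, min_area_px=20), gt))
print(f"held-out mean DSC: raw {np.mean(raw):.3f}, post-processed {np.mean(post):.3f}")
print(
    "\nThe post-processing step (morphological open/close, hole filling,"
    "\nsmall-component removal) trades a little pixel overlap for clean,"
    "\ncountable contours."
)
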