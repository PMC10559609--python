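"""Train a small U-Net on synthetic frames and segment a held-out frame.

Uses a reduced network (64x64 input, 4 base channels, a few epochs) so
the example runs in about a minute on one CPU; the full-size
configuration is the same code with input_size=(512, 512).
"""

import numpy as np

from laryngoscreen import (
    Modality,
    SynthConfig,
    TrainConfig,
    UNetSpec,
    build_model,
    generate_frame,
    iou,
    predict,
    render_heatmap,
    train_arrays,
)

cfg = SynthConfig(seed=0, image_size=(64, 64), lesion_area_range=(300, 900),
                  distractor_area_range=(5, 30))
rng = np.random.default_rng(0)
frames = [generate_frame(cfg, cancer=i % 2 == 0,
                         modality=Modality.WLI if i % 4 < 2 else Modality.NBI,
                         rng=rng)
          for i in range(40)]
train_set, test_set = frames[:32], frames[32:]

model = build_model(UNetSpec(base_channels=8, input_size=(64, 64)), seed=0)
tcfg = TrainConfig(epochs=40, batch_size=8, learning_rate=1e-3, seed=0)
model, history = train_arrays(
    model,
    [f.image for f in train_set], [f.mask for f in train_set], tcfg,
    modalities=[f.modality for f in train_set],
)
print("loss per epoch:", " ".join(f"{h:.4f}" for h in history))

ious = []
for f in test_set:
    result = predict(model, f, probability_threshold=0.5)
    if f.mask.any():
        ious.append(iou(result.binary_mask, f.mask))
print(f"held-out IoU on {len(ious)} cancer frames: "
      f"median {np.median(ious):.3f}")
heat = render_heatmap(predict(model, test_set[0]), test_set[0])
print(f"heatmap overlay: {heat.shape} {heat.dtype} "
      "(warm colours = high predicted cancer probability)")
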