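"""Build and train the CNN stage on phantom crops.

The classifier is a convolutional backbone with its top replaced by global
average pooling -> batch normalization -> dropout -> a 2-unit softmax
output. The learning rate decays geometrically from 1e-4 to 1e-5 over 10
epochs. The small tiny_test backbone keeps this example CPU-friendly; the
ResNet backbones share the identical head.
"""

from thyrocascade import (PhantomSpec, TrainConfig, build_classifier,
                          extract_roi, generate_phantom, predict,
                          train_classifier)
from thyrocascade.cnn import build_backbone, count_parameters

n50 = count_parameters(build_backbone("resnet50"), include_nontrainable=True)
print(f"resnet50 backbone #param (incl. running stats): {n50:,}")

spec, net = build_classifier("tiny_test", seed=0)
print(f"tiny_test classifier: {spec.param_count:,} parameters, "
      f"feature shape {spec.feature_shape}")

data = []
for i in range(10):
    for ncal in (0, 12):
        img, label, _ = generate_phantom(
            PhantomSpec(seed=500 + i, n_calcifications=ncal,
                        calcification_radius=6, calcification_spacing=18,
                        nodule_radius=70, calcification_intensity=255.0))
        data.append((extract_roi(img).cropped, label))

model = train_classifier(net, data, TrainConfig(seed=1), spec=spec)
for h in model.history[::3]:
    print(f"epoch {h['epoch']:2d}  lr {h['lr']:.2e}  "
          f"loss {h['loss']:.4f}  acc {h['accuracy']:.2f}")

img, label, _ = generate_phantom(
    PhantomSpec(seed=999, n_calcifications=12, calcification_radius=6,
                calcification_spacing=18, nodule_radius=70,
                calcification_intensity=255.0))
pred, p = predict(model, extract_roi(img).cropped)
print(f"held-out malign phantom -> {pred} (p_malign = {p:.3f})")
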