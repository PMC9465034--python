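"""Train the 56-layer pre-activation residual network on a small separable
3-class insect image set and report test metrics.

The run uses the published recipe (batch 16, Adam 1e-3, online rotation/
shear/flip augmentation) at desk scale: 90 images per class, 32 px, and an
early stop once validation error reaches zero (the best checkpoint cannot
change after that). Expect a couple of minutes on one CPU.
"""

from pestwatch.classifiers import ResNetV2Spec, TrainConfig, train_resnet
from pestwatch.evaluate import confusion, metrics
from pestwatch.preprocess import split
from pestwatch.synthgen import DEFAULT_CLASSES, make_insect_dataset

ds = make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=90, image_size=32,
                         seed=1)
train, val, test = split(ds, (7, 1.5, 1.5), seed=1)
print(f"split sizes: train {len(train)}, val {len(val)}, test {len(test)}")

model = train_resnet(train, val, spec=ResNetV2Spec(depth=56, n_classes=3),
                     tc=TrainConfig(epochs=20, stop_at_zero_val_error=True),
                     seed=1)
print(f"weighted layers: {model.network.weighted_layers}, "
      f"epochs run: {len(model.history)}, best epoch: {model.best_epoch}")
for h in model.history:
    print(f"  epoch {h['epoch']}: train loss {h['train_loss']:.3f}, "
          f"val error {h['val_error']:.3f}")

report = metrics(confusion(test.labels, model.predict(test.images), 3))
print(f"test accuracy: {100 * report.accuracy:.1f}%")
for name, f1 in zip(ds.class_names, report.f1):
    print(f"  F1 {name}: {100 * f1:.1f}%")
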