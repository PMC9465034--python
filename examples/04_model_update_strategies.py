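"""The three strategies for updating a trained identifier with new field
data: transfer learning on the rebalanced field set, filling mixing, and
symmetric mixing.

A small "lab" model is trained first. A color-shifted 4-class "field" set
stands in for new conditions: the three species are scarce while the
non-target/noise class is oversized, as in real trap data. The fourth class
is downsampled to a quota for transfer learning; filling mixing pads the
target classes with lab images up to the fourth class's size; symmetric
mixing doubles every class with equal lab/field halves. Printed: the class
counts each rule forces and the test accuracy of each updated model.
"""

import numpy as np

from pestwatch.classifiers import (ResNetV2Spec, TrainConfig, train_resnet,
                                   transfer_update)
from pestwatch.preprocess import (build_dataset2_1, filling_mix, split,
                                  symmetric_mix)
from pestwatch.synthgen import ClassSpec, DEFAULT_CLASSES, make_insect_dataset

SPEC = ResNetV2Spec(depth=8, widths=(8, 12, 16), n_classes=3)

lab = make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=120, image_size=32,
                          seed=5)
lab_train, lab_val, _ = split(lab, (7, 1.5, 1.5), seed=5)
base = train_resnet(lab_train, lab_val, spec=SPEC,
                    tc=TrainConfig(epochs=25, stop_at_zero_val_error=True),
                    seed=5)
print(f"lab model: val accuracy {base.history[-1]['val_accuracy']:.2f} "
      f"after {len(base.history)} epochs")

shifted = [ClassSpec(c.class_name, tuple(np.add(c.body_color_mean, (10, -8, 6))),
                     c.body_color_sigma, c.texture_period, c.shape_elongation,
                     c.size_px, c.distorted) for c in DEFAULT_CLASSES]
field = make_insect_dataset(shifted, n_per_class=(30, 30, 30, 120),
                            image_size=32, seed=6)
print(f"field set: class counts {field.class_counts().tolist()}")
field_train, field_val, field_test = split(field, (6, 2, 2), seed=6)

# transfer learning uses the rebalanced field set (fourth class downsampled)
field21 = build_dataset2_1(field, n_fourth=20, seed=6)
f_train, f_val, f_test = split(field21, (6, 2, 2), seed=6)
print(f"rebalanced field set: class counts {field21.class_counts().tolist()}")

tc = TrainConfig(epochs=8)
spec4 = ResNetV2Spec(depth=8, widths=(8, 12, 16), n_classes=4)
t_model = transfer_update(base, f_train, f_val, n_classes_new=4, tc=tc, seed=6)
print(f"transfer update: test accuracy {t_model.accuracy(f_test):.2f}")

filled = filling_mix(lab_train, field_train, seed=6)
print(f"filling mix class counts: {filled.class_counts().tolist()}")
fm_model = train_resnet(filled, f_val, spec=spec4, tc=tc, seed=6)
print(f"filling-mix model: test accuracy {fm_model.accuracy(f_test):.2f}")

pool = field.subset(np.setdiff1d(np.flatnonzero(field.labels == 3),
                                 np.flatnonzero(np.isin(field.ids,
                                                        field21.ids))))
sym = symmetric_mix(lab_train, f_train, pool, seed=6)
print(f"symmetric mix class counts: {sym.class_counts().tolist()}")
sm_model = train_resnet(sym, f_val, spec=spec4, tc=tc, seed=6)
print(f"symmetric-mix model: test accuracy {sm_model.accuracy(f_test):.2f}")
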