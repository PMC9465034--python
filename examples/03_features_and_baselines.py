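"""Hand-crafted features with the classical baselines: extract the
30-dimensional color/texture/shape descriptor per insect ROI, keep the
features a gradient-boosted ensemble ranks above mean importance, then train
the PSO-optimized Gaussian SVM and the BPNN on the selected columns.

Printed: how many (and which) features survive selection, the PSO optimum
(gamma, C) with its cross-validated accuracy, and the BPNN's fold-averaged
accuracy.
"""

import numpy as np

from pestwatch.classifiers import BPNNConfig, PSOConfig, train_bpnn, train_pso_svm
from pestwatch.features import FEATURE_NAMES, extract, select_features
from pestwatch.synthgen import DEFAULT_CLASSES, make_insect_dataset

ds = make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=60, image_size=48,
                         seed=2)
X = np.empty((len(ds), 30))
for i, img in enumerate(ds.images):
    mask = img.astype(float).mean(axis=-1) > 60  # body is brighter than bg
    X[i] = extract(img, mask).values
y = ds.labels

sel = select_features(X, y, seed=0, names=FEATURE_NAMES)
print(f"features kept: {len(sel.selected)} of 30 "
      f"(mean-importance threshold {sel.threshold:.4f})")
for i in sel.selected:
    print(f"  {FEATURE_NAMES[i]:24s} importance {sel.importances[i]:.4f}")

Xs = X[:, sel.selected]
svm = train_pso_svm(Xs, y, PSOConfig(swarm_size=10, iterations=10), seed=0)
print(f"PSO-SVM optimum: gamma {svm.gamma:.3g}, C {svm.C:.3g}, "
      f"CV accuracy {100 * svm.fitness:.1f}%")

cfg = BPNNConfig(n_input=Xs.shape[1], n_hidden=3, n_output=3, epochs=300)
bp = train_bpnn((Xs - Xs.mean(0)) / Xs.std(0), y, cfg, seed=0)
print(f"BPNN 10-fold CV accuracy: {100 * bp.cv_accuracy:.1f}%")
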