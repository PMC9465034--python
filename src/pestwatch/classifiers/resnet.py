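"""56-layer full pre-activation residual network (ResNet V2), CIFAR-style.

Each residual unit computes ``x_{l+1} = h(x_l) + F(x_l, W_l)`` with an
identity skip ``h(x_l) = x_l`` and a residual branch
``F = conv(relu(bn(conv(relu(bn(x))))))`` — batch norm and activation come
*before* each convolution. With identity skips the activation reaching any
deeper unit L is the shallow activation plus the sum of the intervening
residual branches, ``x_L = x_l + sum_i F(x_i, W_i)``, and the gradient
through the stack carries an additive identity term — the property that lets
a 56-layer network train without the signal dying. Both identities are
checked numerically in the test suite.

Depth follows the 6n+2 arithmetic: a stem convolution, three stages of n
two-convolution units at widths (16, 32, 64), and a dense softmax head.
Projection shortcuts (1x1, stride 2) appear only at the two stage boundaries
where shapes change and are excluded from the depth count, as is
conventional.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from ..nn import (Adam, BatchNorm2d, Conv2d, Dense, GlobalAvgPool, ReLU,
                  softmax, softmax_cross_entropy)
from ..preprocess import LabeledImageSet, apply_augment, sample_augment

__all__ = [
    "ResNetV2Spec",
    "TrainConfig",
    "ResidualUnit",
    "ResNetV2",
    "build_resnet_v2",
    "TrainedClassifier",
    "train_resnet",
    "transfer_update",
]


@dataclass(frozen=True)
class ResNetV2Spec:
    """Architecture: depth must be 6n+2 (56 -> 9 units per stage)."""

    depth: int = 56
    widths: tuple[int, int, int] = (16, 32, 64)
    n_classes: int = 3
    in_channels: int = 3

    @property
    def units_per_stage(self) -> int:
        if self.depth < 8 or (self.depth - 2) % 6:
            lo = 6 * max((self.depth - 2) // 6, 1) + 2
            raise ValueError(
                f"depth must be 6n+2; nearest valid depths are {lo} and {lo + 6}")
        return (self.depth - 2) // 6


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe. Defaults are the full recipe (batch 16, Adam at 1e-3,
    200 epochs, online augmentation); reduce ``epochs`` for desk-scale runs.

    ``stop_at_zero_val_error``: the checkpoint criterion is minimum
    validation error with ties to the earlier epoch, so once validation error
    reaches 0 the saved best model can never change; this flag stops training
    at that point instead of spending the remaining epochs.
    """

    batch_size: int = 16
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 200
    augment: bool = True
    max_shear: float = 0.5
    stop_at_zero_val_error: bool = False


class ResidualUnit:
    """Full pre-activation unit: BN-ReLU-conv, BN-ReLU-conv, plus skip."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.bn1 = BatchNorm2d(in_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng, dtype=dtype)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, pad=0,
                               rng=rng, dtype=dtype)

    @property
    def identity_skip(self) -> bool:
        return self.proj is None

    def params(self):
        ps = (self.bn1.params() + self.conv1.params() + self.bn2.params()
              + self.conv2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def branch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """The residual branch F(x, W) alone (no skip)."""
        a = self.relu1.forward(self.bn1.forward(x, train))
        h = self.conv1.forward(a)
        h = self.relu2.forward(self.bn2.forward(h, train))
        return self.conv2.forward(h)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(x, train))
        h = self.conv1.forward(a)
        h = self.relu2.forward(self.bn2.forward(h, train))
        h = self.conv2.forward(h)
        skip = x if self.proj is None else self.proj.forward(a)
        return skip + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv2.backward(dy)
        dh = self.bn2.backward(self.relu2.backward(dh))
        da = self.conv1.backward(dh)
        if self.proj is None:
            dx = self.bn1.backward(self.relu1.backward(da))
            return dx + dy
        da = da + self.proj.backward(dy)
        return self.bn1.backward(self.relu1.backward(da))


class ResNetV2:
    def __init__(self, spec: ResNetV2Spec, rng: np.random.Generator,
                 dtype=np.float32):
        n = spec.units_per_stage
        self.spec = spec
        self.stem = Conv2d(spec.in_channels, spec.widths[0], 3, rng=rng,
                           dtype=dtype)
        self.units: list[ResidualUnit] = []
        in_ch = spec.widths[0]
        for s, width in enumerate(spec.widths):
            for u in range(n):
                stride = 2 if (s > 0 and u == 0) else 1
                self.units.append(ResidualUnit(in_ch, width, stride, rng,
                                               dtype=dtype))
                in_ch = width
        self.final_bn = BatchNorm2d(in_ch, dtype=dtype)
        self.final_relu = ReLU()
        self.pool = GlobalAvgPool()
        self.head = Dense(in_ch, spec.n_classes, rng=rng, dtype=dtype)

    # -- bookkeeping ------------------------------------------------------
    @property
    def weighted_layers(self) -> int:
        """Stem + two convolutions per unit + head (projection shortcuts are
        not counted, per the usual depth arithmetic)."""
        return 1 + 2 * len(self.units) + 1

    def params(self):
        ps = self.stem.params()
        for u in self.units:
            ps += u.params()
        ps += self.final_bn.params() + self.head.params()
        return ps

    def get_state(self):
        state = [p.v.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state) -> None:
        ps = self.params()
        for p, v in zip(ps, state[:len(ps)]):
            p.v[...] = v
        rest = state[len(ps):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self):
        bns = []
        for u in self.units:
            bns += [u.bn1, u.bn2]
        bns.append(self.final_bn)
        return bns

    def zero_residual_branches(self) -> None:
        """Zero every branch's final convolution so F(x, W) = 0 everywhere."""
        for u in self.units:
            u.conv2.W.v[...] = 0

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.stem.forward(x)
        for u in self.units:
            h = u.forward(h, train)
        h = self.final_relu.forward(self.final_bn.forward(h, train))
        return self.head.forward(self.pool.forward(h))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.pool.backward(self.head.backward(dlogits))
        dh = self.final_bn.backward(self.final_relu.backward(dh))
        for u in reversed(self.units):
            dh = u.backward(dh)
        return self.stem.backward(dh)


def build_resnet_v2(spec: ResNetV2Spec = ResNetV2Spec(),
                    seed: int = 0) -> ResNetV2:
    """Build a full pre-activation residual network from its spec."""
    spec.units_per_stage  # validates depth
    return ResNetV2(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """A trained network plus the input statistics it expects and its
    training history (epoch, train loss, val loss/error)."""

    network: ResNetV2
    class_names: list[str]
    norm_mean: np.ndarray
    norm_std: np.ndarray
    history: list[dict]
    best_epoch: int

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            x = _prep(images[i:i + batch_size], self.norm_mean, self.norm_std)
            out.append(softmax(self.network.forward(x, train=False)))
        return np.concatenate(out)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def accuracy(self, dataset: LabeledImageSet) -> float:
        return float((self.predict(dataset.images) == dataset.labels).mean())


def _prep(images: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    x = images.astype(np.float32) / 255.0
    x = (x - mean) / std
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def train_resnet(train: LabeledImageSet, val: LabeledImageSet,
                 spec: ResNetV2Spec | None = None,
                 tc: TrainConfig = TrainConfig(), seed: int = 0,
                 network: ResNetV2 | None = None) -> TrainedClassifier:
    """Train (or fine-tune, if ``network`` is given) on ``train``, computing
    the validation error once per epoch and keeping the best checkpoint
    (minimum validation error, ties to the earlier epoch)."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty training or validation split")
    if spec is None:
        spec = ResNetV2Spec(n_classes=train.n_classes)
    if network is None:
        network = build_resnet_v2(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)

    x = train.images.astype(np.float32) / 255.0
    norm_mean = x.mean(axis=(0, 1, 2))
    norm_std = np.maximum(x.std(axis=(0, 1, 2)), 1e-3)

    opt = Adam(network.params(), lr=tc.lr, beta1=tc.beta1, beta2=tc.beta2)
    model = TrainedClassifier(network=network, class_names=train.class_names,
                              norm_mean=norm_mean, norm_std=norm_std,
                              history=[], best_epoch=-1)
    best_err = np.inf
    best_state = None

    for epoch in range(tc.epochs):
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            imgs = train.images[idx]
            if tc.augment:
                imgs = np.stack([
                    apply_augment(im, sample_augment(rng, tc.max_shear))
                    for im in imgs])
            xb = _prep(imgs, norm_mean, norm_std)
            logits = network.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, train.labels[idx])
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)

        val_p = model.predict_proba(val.images)
        val_pred = val_p.argmax(axis=1)
        val_err = float((val_pred != val.labels).mean())
        val_loss = float(-np.log(np.maximum(
            val_p[np.arange(len(val)), val.labels].astype(np.float64),
            1e-300)).mean())
        model.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                              "val_loss": val_loss, "val_error": val_err,
                              "val_accuracy": 1.0 - val_err})
        if val_err < best_err:
            best_err = val_err
            best_state = network.get_state()
            model.best_epoch = epoch
        if tc.stop_at_zero_val_error and best_err == 0.0:
            break

    if best_state is not None:
        network.set_state(best_state)
    return model


def transfer_update(base: TrainedClassifier, new_train: LabeledImageSet,
                    new_val: LabeledImageSet, n_classes_new: int,
                    tc: TrainConfig = TrainConfig(), seed: int = 0
                    ) -> TrainedClassifier:
    """Update a trained model for new field data: keep every convolutional
    and normalization parameter, drop the dense head and rebuild it for
    ``n_classes_new`` outputs, then retrain all parameters on the new data.

    The rebuilt head starts at zero: its logits are uniform, and no gradient
    reaches the transferred convolutional weights until the head has moved
    off zero, which protects the inherited features from the large,
    uninformative gradients a randomly initialized head produces in the
    first steps of fine-tuning."""
    old_spec = base.network.spec
    if new_train.n_classes != n_classes_new:
        raise ValueError("new_train class count disagrees with n_classes_new")
    spec = replace(old_spec, n_classes=n_classes_new)
    net = build_resnet_v2(spec, seed=seed)
    # copy everything except the head (parameter lists align because only the
    # head's shape changed)
    src = base.network.params()
    dst = net.params()
    head_params = set(map(id, net.head.params()))
    src_head = set(map(id, base.network.head.params()))
    src_body = [p for p in src if id(p) not in src_head]
    dst_body = [p for p in dst if id(p) not in head_params]
    if len(src_body) != len(dst_body):
        raise ValueError("base architecture is incompatible")
    for s, d in zip(src_body, dst_body):
        if s.v.shape != d.v.shape:
            raise ValueError("base architecture is incompatible")
        d.v[...] = s.v
    for bn_src, bn_dst in zip(base.network._batchnorms(), net._batchnorms()):
        bn_dst.running_mean[...] = bn_src.running_mean
        bn_dst.running_var[...] = bn_src.running_var
    net.head.W.v[...] = 0
    net.head.b.v[...] = 0
    return train_resnet(new_train, new_val, spec=spec, tc=tc, seed=seed,
                        network=net)
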