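"""Image branch: rasterized digit sequences, synthetic micrographia
pre-training, fine-tuning with layer freezing, and CNN embeddings.

The finished pen trace is treated as an offline-handwriting problem:
pen-down strokes are rendered as anti-aliased white polylines on a
black 144×216 raster (centered, isotropically scaled).  A compact
convolutional network is first pre-trained to tell apart synthetic
digit sequences with and without micrographia -- sequences whose
digits shrink linearly from a random onset digit (0-5) down to half
size at digit 9, randomly rotated by one of {−15, −5, 0, 5, 15}
degrees -- and then fine-tuned on labeled subject images under one of
four freezing schemes.  The flattened output of the last convolutional
block (1944 dimensions) is the per-subject embedding fed to the SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from scribepd._cnn import (
    FREEZING_SCHEMES,
    HEAD_LAYERS,
    ConvNet,
    TrainConfig,
)
from scribepd.io_formats import TabletRecording
from scribepd.static_representation import StaticVector
from scribepd.synthetic_data import GlyphBank, default_glyph_bank, plan_sequence

IMG_H, IMG_W = 144, 216
ROTATION_SET = (-15.0, -5.0, 0.0, 5.0, 15.0)

MicrographiaNet = ConvNet  # public alias for the image-branch network


@dataclass
class SequenceImage:
    """144×216 grayscale raster of a digit sequence with its label."""

    pixels: np.ndarray
    label: str = "unknown"  # modified | non_modified | PD | HC | unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMG_H, IMG_W):
            raise ValueError(
                f"sequence images must be {IMG_H}x{IMG_W}, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")


@dataclass
class MicrographiaParams:
    """Size-reduction law parameters of one modified sequence."""

    onset_digit: int
    final_scale: float = 0.5
    rotation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.onset_digit <= 5:
            raise ValueError("onset_digit must lie in [0, 5]")
        if self.rotation not in ROTATION_SET:
            raise ValueError(f"rotation must be one of {ROTATION_SET}")


@dataclass
class CNNConfig:
    """Architecture and training configuration of the image branch."""

    filters: tuple[int, int, int] = (16, 8, 4)
    kernel: int = 5
    fc_sizes: tuple[int, int, int] = (512, 64, 2)
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 8
    patience: int = 3
    freezing_scheme: str = "semi_frozen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freezing_scheme not in FREEZING_SCHEMES:
            raise ValueError(
                f"unknown freezing scheme {self.freezing_scheme!r}; "
                f"expected one of {sorted(FREEZING_SCHEMES)}")

    def train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, epochs=self.epochs,
                           batch_size=self.batch_size,
                           patience=self.patience, seed=self.seed)


def scale_sequence(onset: int) -> np.ndarray:
    """Per-digit size factors of a modified sequence.

    Digits before ``onset`` keep scale 1; from the onset the scale
    decreases linearly and reaches exactly 0.5 at digit 9.
    """
    if not isinstance(onset, (int, np.integer)) or not 0 <= onset <= 5:
        raise ValueError(f"onset must be an integer in [0, 5], got {onset!r}")
    d = np.arange(10, dtype=float)
    scales = np.ones(10)
    tail = d >= onset
    scales[tail] = 1.0 - 0.5 * (d[tail] - onset) / (9 - onset)
    return scales


def render_strokes(strokes: list[np.ndarray], margin: int = 10,
                   stroke_width: int = 2, supersample: int = 3) -> np.ndarray:
    """Rasterize polylines (tablet coordinates, y up) to a 144×216 image.

    The trace is centered and isotropically scaled to fit inside the
    margins; rendering draws at ``supersample`` resolution and
    downsamples with a Lanczos filter for anti-aliasing.  White ink on
    black background, intensities in [0, 1].
    """
    pts = np.vstack(strokes)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    scale = min((IMG_W - 2 * margin) / span[0], (IMG_H - 2 * margin) / span[1])
    center = (lo + hi) / 2

    ss = supersample
    img = Image.new("L", (IMG_W * ss, IMG_H * ss), 0)
    draw = ImageDraw.Draw(img)
    width = max(1, round(stroke_width * ss))
    for s in strokes:
        px = (s[:, 0] - center[0]) * scale + IMG_W / 2
        py = IMG_H / 2 - (s[:, 1] - center[1]) * scale  # y up -> row down
        coords = [(float(a) * ss, float(b) * ss) for a, b in zip(px, py)]
        if len(coords) == 1:
            coords = coords * 2
        draw.line(coords, fill=255, width=width, joint="curve")
    small = img.resize((IMG_W, IMG_H), Image.LANCZOS)
    return np.clip(np.asarray(small, dtype=float) / 255.0, 0.0, 1.0)


def render_recording(rec: TabletRecording, margin: int = 10,
                     stroke_width: int = 2) -> SequenceImage:
    """Render the pen-down trace of a recording; in-air samples are omitted."""
    on = rec.pressure > 0
    if not on.any():
        raise ValueError(f"recording {rec.subject_id} has no on-surface samples")
    edges = np.flatnonzero(np.diff(on.astype(int)))
    bounds = [0, *(int(e) + 1 for e in edges), len(on)]
    strokes = [
        np.column_stack([rec.x[a:b], rec.y[a:b]])
        for a, b in zip(bounds[:-1], bounds[1:]) if on[a]
    ]
    pixels = render_strokes(strokes, margin=margin, stroke_width=stroke_width)
    return SequenceImage(pixels, label=rec.condition.value)


def _rotate(pixels: np.ndarray, degrees: float) -> np.ndarray:
    if degrees == 0.0:
        return pixels
    out = ndimage.rotate(pixels, degrees, reshape=False, order=1,
                         mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


@dataclass
class PretrainCorpus:
    """Labeled synthetic sequences with a fixed train/test split."""

    images: np.ndarray          # (n, 144, 216)
    labels: np.ndarray          # 1 = modified, 0 = non_modified
    rotations: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    label_names: tuple[str, str] = ("non_modified", "modified")

    def __len__(self) -> int:
        return len(self.images)


def make_pretrain_corpus(
    n_total: int,
    glyphs: "GlyphBank | None" = None,
    seed: int = 0,
    train_fraction: float = 6 / 7,
) -> PretrainCorpus:
    """Generate the micrographia pre-training corpus.

    Exactly half the sequences are modified (linear shrink from a
    random onset in [0, 5] to half size at digit 9) and half are not;
    all are rotated by an angle drawn from {−15, −5, 0, 5, 15} degrees.
    Mild per-digit size and baseline jitter provides writer-like
    variability.  Deterministic for a fixed seed.
    """
    if n_total % 2 != 0:
        raise ValueError(f"n_total must be even, got {n_total}")
    if glyphs is None:
        glyphs = default_glyph_bank()
    rng = np.random.default_rng(seed)
    n_half = n_total // 2
    labels = np.array([0] * n_half + [1] * n_half)
    order = rng.permutation(n_total)
    labels = labels[order]

    images = np.empty((n_total, IMG_H, IMG_W), dtype=float)
    rotations = np.empty(n_total)
    for i in range(n_total):
        rotation = float(rng.choice(ROTATION_SET))
        scale_jitter = rng.uniform(0.88, 1.12, size=10)
        baseline = rng.uniform(-0.06, 0.06, size=10) * 1000.0
        if labels[i] == 1:
            onset = int(rng.integers(0, 6))
            scales = scale_sequence(onset)
        else:
            scales = np.ones(10)
        plan = plan_sequence(glyphs, scales, digit_scale_jitter=scale_jitter,
                             baseline_offsets=baseline)
        strokes = [s.points for digit in plan for s in digit]
        images[i] = _rotate(render_strokes(strokes), rotation)
        rotations[i] = rotation

    split = rng.permutation(n_total)
    n_train = int(round(train_fraction * n_total))
    return PretrainCorpus(images, labels, rotations,
                          train_idx=np.sort(split[:n_train]),
                          test_idx=np.sort(split[n_train:]))


def build_network(config: "CNNConfig | None" = None) -> ConvNet:
    cfg = config or CNNConfig()
    return ConvNet(input_hw=(IMG_H, IMG_W), filters=cfg.filters,
                   fc_sizes=cfg.fc_sizes, seed=cfg.seed)


def pretrain_cnn(corpus: PretrainCorpus,
                 config: "CNNConfig | None" = None) -> tuple[ConvNet, float]:
    """Train the network to detect micrographia on synthetic sequences.

    Returns the trained model and its held-out accuracy on the corpus
    test split.
    """
    cfg = config or CNNConfig()
    if len(np.unique(corpus.labels)) < 2:
        raise ValueError("pre-training corpus must contain both labels")
    model = build_network(cfg)
    xtr = corpus.images[corpus.train_idx]
    ytr = corpus.labels[corpus.train_idx]
    xte = corpus.images[corpus.test_idx]
    yte = corpus.labels[corpus.test_idx]
    model.fit(xtr, ytr, cfg.train_config(), val_images=xte, val_labels=yte)
    acc = float(np.mean(model.predict_proba(xte).argmax(axis=1) == yte))
    return model, acc


def embed_images(model: ConvNet, images: "np.ndarray | list[SequenceImage]",
                 labels: "list[str] | None" = None) -> list[StaticVector]:
    """Flattened last-conv-layer embeddings as StaticVectors."""
    if len(images) and isinstance(images[0], SequenceImage):
        arr = np.stack([im.pixels for im in images])
    else:
        arr = np.asarray(images, dtype=float)
    emb = model.embed(arr)
    names = [f"cnn.{i}" for i in range(emb.shape[1])]
    return [StaticVector(names, row, "cnn_embedding") for row in emb]


def finetune_and_embed(
    model: ConvNet,
    images: "np.ndarray | list[SequenceImage]",
    labels: np.ndarray,
    scheme: str = "semi_frozen",
    config: "CNNConfig | None" = None,
) -> tuple[ConvNet, list[StaticVector]]:
    """Fine-tune a copy of a pre-trained model and embed the images.

    The freezing scheme fixes which convolutional layers may move
    (fully_frozen: none; partially_frozen: conv1; semi_frozen:
    conv1+conv2; unfrozen: all three); the dense head is always
    trainable.  The original model is left untouched.
    """
    if scheme not in FREEZING_SCHEMES:
        raise ValueError(f"unknown freezing scheme {scheme!r}; "
                         f"expected one of {sorted(FREEZING_SCHEMES)}")
    cfg = config or CNNConfig(freezing_scheme=scheme, epochs=5)
    if len(images) and isinstance(images[0], SequenceImage):
        arr = np.stack([im.pixels for im in images])
    else:
        arr = np.asarray(images, dtype=float)
    tuned = model.clone()
    trainable = set(FREEZING_SCHEMES[scheme]) | set(HEAD_LAYERS)
    tuned.fit(arr, np.asarray(labels, dtype=int), cfg.train_config(),
              trainable=trainable)
    return tuned, embed_images(tuned, arr)


def make_fold_embedder(model: ConvNet, images: np.ndarray, labels: np.ndarray,
                       scheme: str, config: "CNNConfig | None" = None):
    """Per-fold embedding factory for cross-validated image pipelines.

    Returns a callable (train_idx, test_idx) -> (X_train, X_test) that
    fine-tunes a fresh copy of the pre-trained model on the training
    subjects only, then embeds both portions.  Under ``fully_frozen``
    the embeddings do not depend on head fine-tuning (they are the conv
    stack's output), so the pre-trained model embeds directly.
    """
    arr = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=int)

    def embedder(train_idx, test_idx):
        if scheme == "fully_frozen":
            tuned = model
        else:
            cfg = config or CNNConfig(freezing_scheme=scheme, epochs=5)
            tuned = model.clone()
            tuned.fit(arr[train_idx], y[train_idx], cfg.train_config(),
                      trainable=set(FREEZING_SCHEMES[scheme]) | set(HEAD_LAYERS))
        return tuned.embed(arr[train_idx]), tuned.embed(arr[test_idx])

    return embedder
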