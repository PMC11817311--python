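"""Fixed-length per-subject representations of dynamic feature sets.

Variable-length vector features are collapsed to a static vector either
with four statistical functionals (mean, standard deviation, skewness,
excess kurtosis) or by fitting a diagonal-covariance Gaussian mixture
to the stacked feature frames and concatenating its means and diagonal
covariances -- the GMM supervector λ of length M × F × 2, where M is
the number of mixture components and F the number of vector features.
Scalar features are appended unchanged in both cases.

Conventions: standard deviation uses the n−1 denominator; skewness and
kurtosis are bias-uncorrected moment ratios with the Fisher
(excess-kurtosis) convention, and both are defined as 0 for a constant
signal.  Mixture components are sorted canonically (descending weight,
ties broken by the first mean coordinate) so the supervector does not
depend on the fitter's internal component permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from scribepd.dynamic_features import FeatureMatrix

FUNCTIONAL_NAMES = ("mean", "std", "skew", "kurt")


@dataclass
class StaticVector:
    """Named fixed-length representation of one subject."""

    names: list[str]
    values: np.ndarray
    provenance: str  # functionals | gmm_supervector | cnn_embedding | fusion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError(
                f"{len(self.names)} names for {len(self.values)} values")
        if len(set(self.names)) != len(self.names):
            raise ValueError("dimension labels must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise ValueError(f"non-finite values in dimensions {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GMMSpec:
    """Configuration of the supervector mixture fit.

    M is even in [2, 30] (M = 1 is additionally allowed as the
    degenerate single-Gaussian case used for closed-form checks).
    ``variance_floor`` scales the covariance regularization relative to
    the mean per-column variance of the frame matrix.
    """

    M: int
    seed: int = 0
    variance_floor: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        valid = self.M == 1 or (2 <= self.M <= 30 and self.M % 2 == 0)
        if not valid:
            raise ValueError(
                f"M must be 1 or an even number in [2, 30], got {self.M}")
        if not self.variance_floor > 0:
            raise ValueError("variance_floor must be positive")


def moment_functionals(v: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd with n−1, skewness g1, excess kurtosis g2) of a signal."""
    v = np.asarray(v, dtype=float)
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    c = v - m
    m2 = float(np.mean(c ** 2))
    if m2 == 0.0:
        return m, sd, 0.0, 0.0
    skew = float(np.mean(c ** 3) / m2 ** 1.5)
    kurt = float(np.mean(c ** 4) / m2 ** 2 - 3.0)
    return m, sd, skew, kurt


def functionals(fm: FeatureMatrix) -> StaticVector:
    """Four functionals per vector feature, scalars appended unchanged.

    Labels are ``<feature>.<functional>`` sorted canonically; scalar
    labels follow, also sorted.
    """
    names: list[str] = []
    values: list[float] = []
    for fname in sorted(fm.vectors):
        v = fm.vectors[fname]
        if v.size == 0:
            raise ValueError(f"vector feature {fname!r} is empty")
        if v.size < 2:
            raise ValueError(
                f"vector feature {fname!r} needs >= 2 samples for functionals")
        for func_name, val in zip(FUNCTIONAL_NAMES, moment_functionals(v)):
            names.append(f"{fname}.{func_name}")
            values.append(val)
    for sname in sorted(fm.scalars):
        names.append(sname)
        values.append(float(fm.scalars[sname]))
    return StaticVector(names, np.array(values), "functionals")


def build_frame_matrix(
    fms: "list[FeatureMatrix] | FeatureMatrix",
) -> tuple[np.ndarray, list[str], dict[str, float]]:
    """Stack vector features of one subject into a (time × F) matrix.

    Differencing makes tiers progressively shorter, so every vector is
    right-truncated to the shortest length across the given feature
    matrices; columns follow the canonical sorted name order.  Returns
    (frames, column names, merged scalars).
    """
    if isinstance(fms, FeatureMatrix):
        fms = [fms]
    vectors: dict[str, np.ndarray] = {}
    scalars: dict[str, float] = {}
    for fm in fms:
        for k, v in fm.vectors.items():
            if k in vectors:
                raise ValueError(f"duplicate vector feature {k!r}")
            vectors[k] = v
        for k, v in fm.scalars.items():
            if k in scalars:
                raise ValueError(f"duplicate scalar feature {k!r}")
            scalars[k] = v
    if not vectors:
        raise ValueError("no vector features to stack")
    t = min(len(v) for v in vectors.values())
    names = sorted(vectors)
    frames = np.column_stack([vectors[k][:t] for k in names])
    return frames, names, scalars


def _canonical_order(weights: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Descending weight; ties broken by first mean coordinate ascending."""
    return np.lexsort((means[:, 0], -weights))


def gmm_supervector(
    frames: np.ndarray,
    spec: GMMSpec,
    feature_names: "list[str] | None" = None,
    scalars: "dict[str, float] | None" = None,
) -> StaticVector:
    """Diagonal-covariance GMM supervector of a (time × F) frame matrix.

    The supervector concatenates all component means then all diagonal
    covariances in canonical component order, giving length M × F × 2;
    subject scalars, if given, are appended after it.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValueError("frames must be a 2-D (time × F) matrix")
    t, f = frames.shape
    if t < spec.M:
        raise ValueError(
            f"only {t} frames for M={spec.M} components; use a smaller M")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(f)]
    if len(feature_names) != f:
        raise ValueError("feature_names length must match frame columns")

    reg = spec.variance_floor * max(float(np.var(frames, axis=0).mean()), 1e-12)
    gmm = GaussianMixture(
        n_components=spec.M,
        covariance_type="diag",
        random_state=spec.seed,
        init_params="kmeans",
        reg_covar=reg,
        max_iter=spec.max_iter,
    ).fit(frames)
    if not gmm.converged_ and spec.M > 1:
        raise RuntimeError(
            f"GMM did not converge within {spec.max_iter} iterations")

    order = _canonical_order(gmm.weights_, gmm.means_)
    means = gmm.means_[order]
    covs = gmm.covariances_[order]

    names = [f"gmm.mean.c{k}.{fn}" for k in range(spec.M) for fn in feature_names]
    names += [f"gmm.var.c{k}.{fn}" for k in range(spec.M) for fn in feature_names]
    values = np.concatenate([means.ravel(), covs.ravel()])
    if scalars:
        for sname in sorted(scalars):
            names.append(sname)
            values = np.append(values, float(scalars[sname]))
    return StaticVector(names, values, "gmm_supervector")


def early_fusion(a: StaticVector, b: StaticVector) -> StaticVector:
    """Concatenate two static vectors with disjoint label sets."""
    overlap = set(a.names) & set(b.names)
    if overlap:
        raise ValueError(
            f"label collision in early fusion: {sorted(overlap)[:5]}")
    return StaticVector(
        list(a.names) + list(b.names),
        np.concatenate([a.values, b.values]),
        "fusion",
    )
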