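"""Working-memory load decoding from representational / connectivity features.

Three-class (load 4/6/8) classification with the pipeline used throughout:
per repeat, a stratified 70/30 split within each load; feature
standardization and PCA (components kept up to 99% cumulative explained
variance) fitted on the training fold only and applied to the test fold;
a linear SVM (cost 1, one-vs-one) trained and scored on held-out
accuracy; 100 repeats averaged. Region/direction contrasts are assessed
by a label-permutation test on the accuracy difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import ValidationError

__all__ = [
    "FeatureSet",
    "DecodingResult",
    "build_eed_features",
    "build_ems_features",
    "build_psi_features",
    "decode_load",
    "accuracy_difference_test",
    "accuracy_vs_chance_test",
]


@dataclass
class FeatureSet:
    """Samples x features with load labels."""

    X: np.ndarray
    y: np.ndarray
    sample_unit: str  # trial_pair | trial | channel_pair
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValidationError("X must be (n_samples, n_features) matching y")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing values")
        classes, counts = np.unique(self.y, return_counts=True)
        if np.any(counts < 2):
            raise ValidationError("every class needs >= 2 samples")
        self.classes_ = classes


@dataclass
class DecodingResult:
    """Per-repeat held-out accuracies of the PCA + linear-SVM pipeline."""

    accuracies: np.ndarray
    n_components: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.accuracies.std(ddof=1))


def _stack_maps(maps_by_load: dict[int, np.ndarray], unit: str,
                provenance: dict | None = None) -> FeatureSet:
    xs, ys = [], []
    shape = None
    for load, maps in maps_by_load.items():
        maps = np.asarray(maps, dtype=float)
        if maps.ndim != 3:
            raise ValidationError("expected (n_units, n_rows, n_cols) maps per load")
        if shape is None:
            shape = maps.shape[1:]
        elif maps.shape[1:] != shape:
            raise ValidationError(f"inconsistent map shapes: {maps.shape[1:]} vs {shape}")
        xs.append(maps.reshape(maps.shape[0], -1))
        ys.append(np.full(maps.shape[0], load, dtype=int))
    return FeatureSet(X=np.vstack(xs), y=np.concatenate(ys), sample_unit=unit,
                      provenance=provenance or {})


def build_eed_features(maps_by_load: dict[int, np.ndarray],
                       provenance: dict | None = None) -> FeatureSet:
    """Flatten per-trial-pair EED maps (e.g. 201 x 201 -> 40401 features).

    ``maps_by_load[load]`` stacks the per-pair maps of all participants,
    so 100 pairs x 14 participants gives 1400 samples per load.
    """
    return _stack_maps(maps_by_load, "trial_pair", provenance)


def build_ems_features(maps_by_load: dict[int, np.ndarray],
                       provenance: dict | None = None) -> FeatureSet:
    """Flatten per-trial EMS maps (e.g. 201 x 301 -> 60501 features)."""
    return _stack_maps(maps_by_load, "trial", provenance)


def build_psi_features(z_by_load: dict[int, np.ndarray], direction: str,
                       provenance: dict | None = None) -> FeatureSet:
    """Directional PSI features per channel pair.

    ``z_by_load[load]`` is the (n_channel_pairs, n_freqs) z-scored PSI.
    Only the chosen direction's values are kept (hippocampus-leads keeps
    positive z, amygdala-leads keeps the magnitude of negative z); the
    other direction's bins are zero-filled, so the two feature sets built
    from one PSI result are disjoint by sign.
    """
    if direction not in ("HIP_leads", "AMY_leads"):
        raise ValidationError(f"unknown direction {direction!r}")
    xs, ys = [], []
    for load, z in z_by_load.items():
        z = np.atleast_2d(np.asarray(z, dtype=float))
        feat = np.where(z > 0, z, 0.0) if direction == "HIP_leads" else np.where(z < 0, -z, 0.0)
        xs.append(feat)
        ys.append(np.full(feat.shape[0], load, dtype=int))
    X = np.vstack(xs)
    prov = dict(provenance or {})
    prov["direction"] = direction
    return FeatureSet(X=X, y=np.concatenate(ys), sample_unit="channel_pair",
                      provenance=prov)


def _stratified_split(y: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * idx.size + 1e-9))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def decode_load(fs: FeatureSet, train_frac: float = 0.7, n_repeats: int = 100,
                var_keep: float = 0.99, cost: float = 1.0,
                standardize: bool = True,
                seed: int | np.random.Generator = 0) -> DecodingResult:
    """Repeated stratified 70/30 PCA + linear-SVM load classification.

    PCA (and the optional standardization) are fitted on the training fold
    only; the test fold is projected with the training-fit transform.
    """
    if np.unique(fs.y).size < 2:
        raise ValidationError("need >= 2 classes to decode")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(n_repeats)
    ncomp = np.empty(n_repeats, dtype=int)
    for r in range(n_repeats):
        tr, te = _stratified_split(fs.y, train_frac, rng)
        X_tr, X_te = fs.X[tr], fs.X[te]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr = scaler.transform(X_tr)
            X_te = scaler.transform(X_te)
        pca = PCA(n_components=var_keep, svd_solver="full").fit(X_tr)
        X_tr = pca.transform(X_tr)
        X_te = pca.transform(X_te)
        clf = SVC(kernel="linear", C=cost, decision_function_shape="ovo")
        clf.fit(X_tr, fs.y[tr])
        accs[r] = float(np.mean(clf.predict(X_te) == fs.y[te]))
        ncomp[r] = pca.n_components_
    master = seed if isinstance(seed, int) else -1
    return DecodingResult(accuracies=accs, n_components=ncomp, seed=master)


def _shuffled(fs: FeatureSet, rng: np.random.Generator) -> FeatureSet:
    y = fs.y.copy()
    rng.shuffle(y)
    # bypass class-count validation cost by constructing directly
    out = FeatureSet.__new__(FeatureSet)
    out.X, out.y = fs.X, y
    out.sample_unit, out.provenance = fs.sample_unit, fs.provenance
    return out


def accuracy_difference_test(fsA: FeatureSet, fsB: FeatureSet,
                             n_perm: int = 200, n_repeats: int = 100,
                             seed: int | np.random.Generator = 0,
                             **decode_kwargs) -> tuple[float, float]:
    """Permutation test for a region/direction decoding-accuracy contrast.

    Observed statistic: mean accuracy(A) - mean accuracy(B). The null
    shuffles the load labels of both feature sets and recomputes the
    difference ``n_perm`` times; the two-sided p-value uses +1 smoothing.
    """
    if n_perm < 20:
        raise ValidationError("n_perm < 20 gives too coarse a p-value resolution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = (decode_load(fsA, n_repeats=n_repeats, seed=rng, **decode_kwargs).mean
           - decode_load(fsB, n_repeats=n_repeats, seed=rng, **decode_kwargs).mean)
    null = np.empty(n_perm)
    for p in range(n_perm):
        a = decode_load(_shuffled(fsA, rng), n_repeats=n_repeats, seed=rng, **decode_kwargs)
        b = decode_load(_shuffled(fsB, rng), n_repeats=n_repeats, seed=rng, **decode_kwargs)
        null[p] = a.mean - b.mean
    pval = (np.sum(np.abs(null) >= abs(obs)) + 1) / (n_perm + 1)
    return float(obs), float(pval)


def accuracy_vs_chance_test(fs: FeatureSet, n_perm: int = 200,
                            n_repeats: int = 100,
                            seed: int | np.random.Generator = 0,
                            **decode_kwargs) -> tuple[float, float, float]:
    """Permutation test of decoding accuracy against the label-shuffle null.

    Returns (observed mean accuracy, one-sided p with +1 smoothing, mean
    of the null accuracies). The null mean is the empirical chance level;
    for balanced three-class problems it sits at 1/3.
    """
    if n_perm < 20:
        raise ValidationError("n_perm < 20 gives too coarse a p-value resolution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = decode_load(fs, n_repeats=n_repeats, seed=rng, **decode_kwargs).mean
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = decode_load(_shuffled(fs, rng), n_repeats=n_repeats,
                              seed=rng, **decode_kwargs).mean
    pval = (np.sum(null >= obs) + 1) / (n_perm + 1)
    return float(obs), float(pval), float(null.mean())
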