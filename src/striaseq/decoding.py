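"""Region-identity decoding with balanced, cross-validated LDA.

Each unit contributes one observation: its 12-element vector of mean
peri-event z-scores (or, in the PCA variant, the leading principal-component
scores of its 357-element concatenated z vector). Per repetition the larger
region is subsampled to the smaller region's count, a stratified 10-fold
cross-validation is run, and the mean held-out accuracy recorded; 50
repetitions give the accuracy distribution. The shuffled control repeats
the procedure with region labels permuted once per repetition, and the
permutation p-value compares the mean true accuracy against the shuffled
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .config import AnalysisConfig
from .psth import PeriEventMatrix


@dataclass
class DecodingResult:
    context: str
    true_accuracies: np.ndarray  # one per repetition
    shuffled_accuracies: np.ndarray
    p_value: float

    @property
    def mean_true(self) -> float:
        return float(self.true_accuracies.mean())

    @property
    def mean_shuffled(self) -> float:
        return float(self.shuffled_accuracies.mean())


def feature_matrix(
    pems: Sequence[PeriEventMatrix],
    config: AnalysisConfig = AnalysisConfig(),
    feature: str = "window_means",
) -> np.ndarray:
    """Stack the per-unit decoding features into an (n_units, d) matrix."""
    if feature == "window_means":
        return np.array([p.window_means(config) for p in pems])
    if feature == "concat":
        return np.array([p.concat_vector for p in pems])
    raise ValueError(f"unknown feature set {feature!r}")


def _lda() -> LinearDiscriminantAnalysis:
    # pooled-covariance LDA; tiny shrinkage guards near-singular folds
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)


def _cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    n_pcs: Optional[int] = None,
) -> float:
    """Mean held-out accuracy of one stratified K-fold pass."""
    for attempt in range(5):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        try:
            accs = []
            for train, test in skf.split(x, y):
                if len(np.unique(y[train])) < 2:
                    raise ValueError("single-class training fold")
                xtr, xte = x[train], x[test]
                if n_pcs is not None:
                    # PCA fit on the training fold only, to avoid leakage
                    k = min(n_pcs, xtr.shape[0] - 1, xtr.shape[1])
                    if k < n_pcs:
                        warnings.warn(
                            f"n_pcs clipped to rank {k}", stacklevel=2
                        )
                    pca = PCA(n_components=k, random_state=0)
                    xtr = pca.fit_transform(xtr)
                    xte = pca.transform(xte)
                clf = _lda()
                clf.fit(xtr, y[train])
                accs.append(float((clf.predict(xte) == y[test]).mean()))
            return float(np.mean(accs))
        except ValueError:
            if attempt == 4:
                raise
            warnings.warn("degenerate fold; refolding with a new seed", stacklevel=2)
    raise AssertionError("unreachable")


def _balanced_subsample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices subsampling the larger region down to the smaller's count."""
    classes, counts = np.unique(y, return_counts=True)
    n = counts.min()
    keep = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def decode_region(
    features: np.ndarray,
    regions: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    n_pcs: Optional[int] = None,
    context: str = "",
) -> DecodingResult:
    """Balanced cross-validated decoding with its shuffled-label control."""
    features = np.asarray(features, dtype=float)
    regions = np.asarray(regions)
    classes, counts = np.unique(regions, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected two regions, got {list(classes)}")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need at least n_folds={config.n_folds} units per region, "
            f"got {dict(zip(classes, counts))}"
        )
    rng = np.random.default_rng([seed % (2**31), 7])
    true_accs, shuf_accs = [], []
    for _ in range(config.n_decode_reps):
        idx = _balanced_subsample(regions, rng)
        x, y = features[idx], regions[idx]
        true_accs.append(_cv_accuracy(x, y, config.n_folds, rng, n_pcs))
        y_shuf = rng.permutation(y)  # labels only; features untouched
        shuf_accs.append(_cv_accuracy(x, y_shuf, config.n_folds, rng, n_pcs))
    true_accs = np.array(true_accs)
    shuf_accs = np.array(shuf_accs)
    return DecodingResult(
        context=context,
        true_accuracies=true_accs,
        shuffled_accuracies=shuf_accs,
        p_value=permutation_pvalue(true_accs, shuf_accs),
    )


def shuffled_control(
    features: np.ndarray,
    regions: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
) -> np.ndarray:
    """The shuffled-label accuracy distribution alone."""
    return decode_region(features, regions, config, seed=seed).shuffled_accuracies


def permutation_pvalue(true_accs: np.ndarray, shuffled_accs: np.ndarray) -> float:
    """p = (1 + #{shuffled >= mean(true)}) / (n + 1)."""
    true_accs = np.asarray(true_accs, dtype=float)
    shuffled_accs = np.asarray(shuffled_accs, dtype=float)
    if true_accs.size == 0 or shuffled_accs.size == 0:
        raise ValueError("empty accuracy sample")
    if shuffled_accs.size < 20:
        warnings.warn(
            f"only {shuffled_accs.size} shuffles: coarse p-value", stacklevel=2
        )
    n = shuffled_accs.size
    return float((1 + (shuffled_accs >= true_accs.mean()).sum()) / (n + 1))


def ensemble_sweep(
    features: np.ndarray,
    regions: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    sizes: Optional[Sequence[int]] = None,
    n_pcs: Optional[int] = None,
) -> list[DecodingResult]:
    """Decode at each pooled ensemble size; infeasible sizes are skipped."""
    features = np.asarray(features, dtype=float)
    regions = np.asarray(regions)
    sizes = list(sizes if sizes is not None else config.ensemble_sizes)
    rng = np.random.default_rng([seed % (2**31), 11])
    results = []
    for size in sizes:
        if size > len(regions) // 2 or size < 2 * config.n_folds:
            warnings.warn(
                f"ensemble size {size} infeasible for {len(regions)} units; skipped",
                stacklevel=2,
            )
            continue
        accs_t, accs_s = [], []
        for _ in range(config.n_decode_reps):
            # sample size/2 per region without replacement, then 10-fold CV
            keep = []
            for c in np.unique(regions):
                idx = np.nonzero(regions == c)[0]
                take = min(size // 2, len(idx))
                keep.append(rng.choice(idx, size=take, replace=False))
            idx = np.sort(np.concatenate(keep))
            x, y = features[idx], regions[idx]
            accs_t.append(_cv_accuracy(x, y, config.n_folds, rng, n_pcs))
            accs_s.append(_cv_accuracy(x, rng.permutation(y), config.n_folds, rng, n_pcs))
        accs_t, accs_s = np.array(accs_t), np.array(accs_s)
        results.append(
            DecodingResult(
                context=str(size),
                true_accuracies=accs_t,
                shuffled_accuracies=accs_s,
                p_value=permutation_pvalue(accs_t, accs_s),
            )
        )
    return results


def pca_decode(
    pems_or_features,
    regions: Optional[np.ndarray] = None,
    config: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    n_pcs: Optional[int] = None,
    pc_sweep: Optional[Sequence[int]] = None,
):
    """PCA-front-end decoding on the concatenated z vectors.

    With ``pc_sweep`` a list of PC counts, returns ``{n_pcs: DecodingResult}``;
    otherwise a single :class:`DecodingResult` at ``config.n_pcs``.
    """
    if regions is None:
        raise ValueError("regions array is required")
    if hasattr(pems_or_features[0], "concat_vector"):
        features = feature_matrix(pems_or_features, config, feature="concat")
    else:
        features = np.asarray(pems_or_features, dtype=float)
    if pc_sweep is not None:
        return {
            k: decode_region(features, regions, config, seed=seed, n_pcs=k,
                             context=f"pcs_{k}")
            for k in pc_sweep
        }
    k = n_pcs if n_pcs is not None else config.n_pcs
    return decode_region(features, regions, config, seed=seed, n_pcs=k,
                         context=f"pcs_{k}")
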