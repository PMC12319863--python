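"""Three-class category decoding from run-wise voxel patterns.

Linear SVM (C = 1, one-vs-one) with leave-one-run-out cross-validation.
Class sizes are unbalanced (16 effector / 8 face / 8 non-effector samples
over 4 runs), so within every training fold the majority classes are
repeatedly subsampled without replacement to the minority-class count
(bootstrap balancing, default 100 draws) and per-draw accuracies are
averaged. The permutation null re-runs the whole procedure under each of
the 420 condition-to-category assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from . import stats
from .cohort import VoxelPatternSet
from .conditions import BODY_PARTS
from .inference import PartitionModel, enumerate_partitions, hypothesized_partition

CHANCE_LEVEL = 1.0 / 3.0


@dataclass
class DecodingSamples:
    """Run-wise decoding samples for one subject."""

    features: np.ndarray  # (n_samples, n_voxels)
    categories: np.ndarray  # (n_samples,) category label strings
    runs: np.ndarray  # (n_samples,) run index
    conditions: np.ndarray  # (n_samples,) condition names


@dataclass
class DecodingResult:
    accuracy: float
    chance: float = CHANCE_LEVEL


@dataclass
class PermutationDecodingResult:
    accuracy: float
    p: float
    null_distribution: np.ndarray  # one accuracy per enumerated model


def build_samples(
    patterns: VoxelPatternSet,
    voxels: np.ndarray | None = None,
    model: PartitionModel | None = None,
) -> DecodingSamples:
    """One sample per (run, body-part condition): 32 samples, labels 16/8/8."""
    if model is None:
        model = hypothesized_partition()
    missing = [c for c in BODY_PARTS if c not in patterns.conditions]
    if missing:
        raise ValueError(f"patterns lack body-part conditions: {missing}")
    idx = [patterns.condition_index(c) for c in BODY_PARTS]
    feats, cats, runs, conds = [], [], [], []
    for r in range(patterns.n_runs):
        for c, cond in zip(idx, BODY_PARTS):
            x = patterns.betas[r, c]
            if voxels is not None:
                x = x[np.asarray(voxels)]
            feats.append(x)
            cats.append(model.category_of(cond))
            runs.append(r)
            conds.append(cond)
    return DecodingSamples(
        features=np.asarray(feats),
        categories=np.asarray(cats),
        runs=np.asarray(runs),
        conditions=np.asarray(conds),
    )


def _balanced_fold_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_bootstrap: int,
    rng: np.random.Generator,
    scale: bool = False,
) -> float:
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("a class is absent from the training fold")
    per_class = {c: np.flatnonzero(y_train == c) for c in classes}
    n_min = min(len(v) for v in per_class.values())
    accs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        keep = np.concatenate(
            [
                rng.choice(members, size=n_min, replace=False)
                for members in per_class.values()
            ]
        )
        Xb, yb = X_train[keep], y_train[keep]
        if scale:
            mu, sd = Xb.mean(axis=0), Xb.std(axis=0)
            sd[sd == 0] = 1.0
            Xb = (Xb - mu) / sd
            Xt = (X_test - mu) / sd
        else:
            Xt = X_test
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xb, yb)
        accs[b] = float((clf.predict(Xt) == y_test).mean())
    return float(accs.mean())


def decode_subject(
    samples: DecodingSamples,
    n_bootstrap: int = 100,
    seed: int = 0,
    scale: bool = False,
) -> DecodingResult:
    """Leave-one-run-out, bootstrap-balanced linear-SVM accuracy.

    Accuracy is the mean proportion correct over held-out predictions,
    bootstrap draws, and folds; reproducible from ``seed`` via per-fold
    substreams.
    """
    run_ids = np.unique(samples.runs)
    if len(run_ids) < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs")
    fold_accs = []
    for fold, test_run in enumerate(run_ids):
        test = samples.runs == test_run
        rng = np.random.default_rng([seed, 86028121, fold])
        fold_accs.append(
            _balanced_fold_accuracy(
                samples.features[~test],
                samples.categories[~test],
                samples.features[test],
                samples.categories[test],
                n_bootstrap,
                rng,
                scale=scale,
            )
        )
    return DecodingResult(accuracy=float(np.mean(fold_accs)))


def decoding_permutation_test(
    patterns: VoxelPatternSet,
    voxels: np.ndarray | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> PermutationDecodingResult:
    """Exhaustive 420-assignment permutation null for one subject.

    Decodes under every enumerated condition-to-category model (the
    hypothesized model is index 0) and reports p = fraction of null
    accuracies >= the hypothesized accuracy, itself included.
    """
    models = enumerate_partitions()
    null = np.empty(len(models))
    for k, model in enumerate(models):
        samples = build_samples(patterns, voxels, model)
        null[k] = decode_subject(samples, n_bootstrap=n_bootstrap, seed=seed).accuracy
    acc = null[0]
    p = float((null >= acc - 1e-12).sum()) / len(models)
    return PermutationDecodingResult(accuracy=float(acc), p=p, null_distribution=null)


def decoding_group_inference(
    accuracies: dict[str, np.ndarray]
) -> dict[str, stats.StatResult]:
    """Group summaries: one-sample t vs chance per group, Welch t between groups."""
    groups = sorted(accuracies)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    out: dict[str, stats.StatResult] = {}
    for g in groups:
        out[f"{g}_vs_chance"] = stats.one_sample_t(
            np.asarray(accuracies[g], dtype=float), CHANCE_LEVEL
        )
    out["between_groups"] = stats.welch_t_raw(
        np.asarray(accuracies[groups[0]], dtype=float),
        np.asarray(accuracies[groups[1]], dtype=float),
    )
    return out
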