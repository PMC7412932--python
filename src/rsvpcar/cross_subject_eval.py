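"""LDA target detection and the random-vs-CAR donor-selection experiment.

A new ("test") subject contributes only a short unlabeled-equivalent
calibration segment — their first few blocks — from which a target ERP is
averaged.  Donor subjects (fully recorded database subjects) are then chosen
either uniformly at random or as the top-N of the CAR Pearson ranking against
that calibration ERP.  A shrinkage-regularized LDA is trained on the pooled
donor epochs and scored on the test subject's remaining (non-calibration)
epochs; performance is the Mann–Whitney AUC of target vs nontarget scores.

Leakage guards are structural: the test subject is never in the donor pool,
and calibration epochs are never scored.  Both facts are asserted at run time
and recorded in the result's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from .containers import ANALYSIS_CHANNELS, EpochSet, ERPWaveform
from .erp_similarity import DEFAULT_SEGMENT, coherent_average, rank_donors
from .preprocess import select_channels


@dataclass(frozen=True)
class FeatureConfig:
    """Epoch -> feature-vector recipe: channel subset, post-stimulus segment,
    and non-overlapping time-bin averaging.

    Defaults (0–800 ms, 50 ms bins, six analysis channels) give
    6 × 16 = 96 features per epoch at 200 Hz.
    """

    segment: tuple[float, float] = (0.0, 800.0)
    bin_width: float = 50.0  # ms
    channels: tuple[str, ...] = ANALYSIS_CHANNELS

    def __post_init__(self) -> None:
        seg_len = self.segment[1] - self.segment[0]
        if seg_len <= 0 or self.bin_width <= 0:
            raise ValueError("segment length and bin_width must be > 0")
        n_bins = seg_len / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError(
                f"bin_width {self.bin_width} ms must divide segment length "
                f"{seg_len} ms"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.segment[1] - self.segment[0]) / self.bin_width))

    def n_features(self) -> int:
        return self.n_bins * len(self.channels)


@dataclass
class TrainedClassifier:
    """Linear discriminant: score(x) = w·x + b, higher = more target-like."""

    weights: np.ndarray
    bias: float
    class_means: np.ndarray  # (2, n_features): row 0 nontarget, row 1 target
    shrinkage: float | str
    n_features: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)
        if self.weights.shape[0] != self.n_features:
            raise ValueError("weight dimension must equal feature dimension")

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"features have {features.shape[1]} columns, classifier "
                f"expects {self.n_features}"
            )
        return features @ self.weights + self.bias


@dataclass
class EvaluationResult:
    """Per-test-subject AUCs for one donor-selection model at one N."""

    model: str  # "random" | "car" | "within_subject" | "naive_cross"
    n_donors: int
    subject_ids: list[str]
    aucs: np.ndarray  # (n_subjects, n_reps)
    seeds: list[int]
    calibration_blocks: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aucs = np.atleast_2d(np.asarray(self.aucs, dtype=np.float64))
        if np.any((self.aucs < 0) | (self.aucs > 1)):
            raise ValueError("AUC values must lie in [0, 1]")
        if self.aucs.shape[0] != len(self.subject_ids):
            raise ValueError("one AUC row per test subject required")

    @property
    def per_subject_auc(self) -> np.ndarray:
        """Mean over repetitions, one value per test subject."""
        return self.aucs.mean(axis=1)

    @property
    def mean_auc(self) -> float:
        return float(self.per_subject_auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.per_subject_auc.std(ddof=1)) if len(self.subject_ids) > 1 else 0.0


@dataclass
class PairedComparison:
    """Normality check plus paired t-test on per-subject AUC differences."""

    model_a: str
    model_b: str
    n: int
    ks_stat_a: float
    ks_p_a: float
    ks_stat_b: float
    ks_p_b: float
    t_stat: float
    p_value: float
    mean_difference: float
    degenerate: bool = False  # zero-variance differences: t undefined


def extract_features(
    epochs: EpochSet, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-averaged feature matrix (n_epochs × n_features) and labels.

    Per epoch: restrict to ``cfg.channels`` and ``cfg.segment``, average
    within consecutive non-overlapping ``bin_width`` bins, concatenate
    channels in order.
    """
    cfg = cfg or FeatureConfig()
    if list(cfg.channels) != list(epochs.channel_names):
        epochs = select_channels(epochs, list(cfg.channels))
    lo = epochs.sample_index(cfg.segment[0])
    hi = epochs.sample_index(cfg.segment[1])
    if lo < 0 or hi > epochs.n_samples or hi <= lo:
        raise ValueError(
            f"segment {cfg.segment} ms outside epoch window {epochs.window}"
        )
    seg = epochs.data[:, :, lo:hi]
    n_bins = cfg.n_bins
    samples_per_bin = seg.shape[2] / n_bins
    if abs(samples_per_bin - round(samples_per_bin)) > 1e-9:
        raise ValueError(
            f"bin_width {cfg.bin_width} ms is not an integer number of "
            f"samples at {epochs.rate} Hz"
        )
    spb = int(round(samples_per_bin))
    binned = seg.reshape(seg.shape[0], seg.shape[1], n_bins, spb).mean(axis=3)
    features = binned.reshape(seg.shape[0], -1).astype(np.float64)
    return features, epochs.labels.astype(np.int8)


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    shrinkage: float | str = "auto",
) -> TrainedClassifier:
    """Shrinkage-regularized LDA (lsqr solver, covariance shrunk toward a
    scaled identity; 'auto' uses Ledoit–Wolf analytic shrinkage).

    Shrinkage keeps the pooled covariance invertible when donor epochs are
    few relative to the ~100-dimensional feature space.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both target and nontarget examples are required")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"need >= 2 samples in class {c}")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(features, labels)
    weights = lda.coef_.ravel()
    bias = float(lda.intercept_[0])
    if np.allclose(weights, 0.0):
        # zero within-class variance (noiseless data): the pooled covariance
        # vanishes and lsqr returns w = 0.  The LDA direction in that limit
        # is the class-mean difference; use it so scores still separate.
        mu0, mu1 = lda.means_
        weights = mu1 - mu0
        bias = float(-weights @ (mu0 + mu1) / 2.0)
    return TrainedClassifier(
        weights=weights,
        bias=bias,
        class_means=lda.means_,
        shrinkage=shrinkage,
        n_features=features.shape[1],
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: probability a random target outscores a random
    nontarget, ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def _pool_epochs(
    epoch_sets: list[EpochSet],
    zscore_donors: bool = False,
    nontarget_keep: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool cached donor features; optionally z-score each donor's features
    by its own statistics, and/or keep only a random fraction of nontarget
    epochs (targets are always kept)."""
    feats, labs = [], []
    for ep in epoch_sets:
        x, y = ep._features_cache
        if zscore_donors:
            sd = x.std(axis=0)
            x = (x - x.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
        if nontarget_keep < 1.0:
            keep = y == 1
            ntg = np.flatnonzero(y == 0)
            n_keep = max(2, int(round(nontarget_keep * len(ntg))))
            keep[(rng or np.random.default_rng()).choice(ntg, n_keep, replace=False)] = True
            x, y = x[keep], y[keep]
        feats.append(x)
        labs.append(y)
    return np.concatenate(feats), np.concatenate(labs)


def evaluate_model(
    cohort: list[EpochSet],
    model: str,
    n_donors: int,
    calibration_blocks: int = 2,
    reps: int = 10,
    seed: int = 0,
    feature_cfg: FeatureConfig | None = None,
    segment: tuple[float, float] = DEFAULT_SEGMENT,
    shrinkage: float | str = "auto",
    zscore_donors: bool = False,
    nontarget_keep: float = 1.0,
) -> EvaluationResult:
    """Leave-one-subject-out donor-selection experiment.

    For each test subject in turn: split off their first
    ``calibration_blocks`` blocks; choose ``n_donors`` donors from the
    remaining subjects — uniformly at random (``reps`` independent draws) or
    as the CAR top-N ranked by Pearson correlation between donor target ERPs
    and the test subject's calibration-only target ERP; train LDA on the
    pooled donor epochs; compute the AUC on the test subject's
    non-calibration epochs.  Calibration epochs are never scored and the test
    subject's epochs are never trained on.

    ``zscore_donors`` standardizes each donor's features by that donor's own
    mean/SD before pooling (off by default: pooling is raw).
    ``nontarget_keep`` < 1 subsamples nontarget training epochs per donor for
    speed; targets are always kept.
    """
    if model not in ("random", "car"):
        raise ValueError(f"model must be 'random' or 'car', got {model!r}")
    n_subjects = len(cohort)
    if n_donors >= n_subjects:
        raise ValueError(
            f"n_donors ({n_donors}) must be < cohort size ({n_subjects})"
        )
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if calibration_blocks < 1:
        raise ValueError("calibration_blocks must be >= 1")
    cfg = feature_cfg or FeatureConfig(channels=tuple(cohort[0].channel_names))
    rng = np.random.default_rng(seed)

    # pre-compute per-subject features and full-session donor ERPs once
    donor_erps: dict[str, ERPWaveform] = {}
    for ep in cohort:
        if ep.block_idx is None:
            raise ValueError(f"subject {ep.subject_id!r} lacks block structure")
        if ep.block_idx.max() + 1 <= calibration_blocks:
            raise ValueError(
                f"subject {ep.subject_id!r} has no non-calibration blocks"
            )
        ep._features_cache = extract_features(ep, cfg)  # type: ignore[attr-defined]
        donor_erps[ep.subject_id] = coherent_average(ep)

    ids = [ep.subject_id for ep in cohort]
    n_reps = reps if model == "random" else 1
    aucs = np.empty((n_subjects, n_reps))
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps * n_subjects)]
    selected: dict[str, list[list[str]]] = {}

    for i, test_ep in enumerate(cohort):
        calib_mask = test_ep.block_idx < calibration_blocks
        eval_ep = test_ep.select(~calib_mask)
        eval_feats, eval_labels = extract_features(eval_ep, cfg)
        pool = [ep for ep in cohort if ep.subject_id != test_ep.subject_id]
        assert all(ep.subject_id != test_ep.subject_id for ep in pool)

        if model == "car":
            calib_ep = test_ep.select(calib_mask)
            calib_erp = coherent_average(calib_ep)
            ranking = rank_donors(
                calib_erp, [donor_erps[ep.subject_id] for ep in pool], segment
            )
            donor_lists = [ranking.top(n_donors)]
        else:
            donor_lists = []
            for rep in range(n_reps):
                rep_rng = np.random.default_rng(rep_seeds[i * n_reps + rep])
                pick = rep_rng.choice(len(pool), size=n_donors, replace=False)
                donor_lists.append([pool[k].subject_id for k in sorted(pick)])
        selected[test_ep.subject_id] = donor_lists

        for rep, donor_ids in enumerate(donor_lists):
            donors = [ep for ep in pool if ep.subject_id in set(donor_ids)]
            assert test_ep.subject_id not in {d.subject_id for d in donors}
            train_x, train_y = _pool_epochs(
                donors, zscore_donors, nontarget_keep,
                np.random.default_rng(rep_seeds[i * n_reps + rep]),
            )
            clf = fit_lda(train_x, train_y, shrinkage)
            scores = clf.decision_scores(eval_feats)
            # provenance guard: only non-calibration epochs are scored
            assert len(scores) == int((~calib_mask).sum())
            aucs[i, rep] = auc(scores, eval_labels)

    for ep in cohort:
        del ep._features_cache  # type: ignore[attr-defined]

    return EvaluationResult(
        model=model,
        n_donors=n_donors,
        subject_ids=ids,
        aucs=aucs,
        seeds=rep_seeds,
        calibration_blocks=calibration_blocks,
        provenance={
            "selected_donors": selected,
            "feature_config": {
                "segment": list(cfg.segment),
                "bin_width": cfg.bin_width,
                "channels": list(cfg.channels),
            },
            "scored_epochs": "non-calibration only",
            "leakage_checked": True,
        },
    )


def compare_models(
    result_a: EvaluationResult, result_b: EvaluationResult
) -> PairedComparison:
    """Kolmogorov–Smirnov normality check on each per-subject AUC sample,
    then a two-sided paired t-test on the per-subject differences."""
    if result_a.subject_ids != result_b.subject_ids:
        raise ValueError("paired comparison requires identical test subjects in order")
    a = result_a.per_subject_auc
    b = result_b.per_subject_auc
    if len(a) < 2:
        raise ValueError("need at least 2 paired samples")

    def _ks(x: np.ndarray) -> tuple[float, float]:
        sd = x.std(ddof=1)
        if sd == 0:
            return float("nan"), float("nan")
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
        return float(stat), float(p)

    ks_a, ksp_a = _ks(a)
    ks_b, ksp_b = _ks(b)
    diff = a - b
    if diff.std(ddof=1) <= 1e-12:  # constant differences: t is undefined
        diff = np.where(np.abs(diff) <= 1e-12, 0.0, diff)
        return PairedComparison(
            model_a=result_a.model,
            model_b=result_b.model,
            n=len(a),
            ks_stat_a=ks_a,
            ks_p_a=ksp_a,
            ks_stat_b=ks_b,
            ks_p_b=ksp_b,
            t_stat=float("nan") if diff.mean() != 0 else 0.0,
            p_value=1.0 if diff.mean() == 0 else float("nan"),
            mean_difference=float(diff.mean()),
            degenerate=diff.mean() != 0,
        )
    t_stat, p = stats.ttest_rel(a, b)
    return PairedComparison(
        model_a=result_a.model,
        model_b=result_b.model,
        n=len(a),
        ks_stat_a=ks_a,
        ks_p_a=ksp_a,
        ks_stat_b=ks_b,
        ks_p_b=ksp_b,
        t_stat=float(t_stat),
        p_value=float(p),
        mean_difference=float(diff.mean()),
    )
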