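"""Coherent averaging and inter-subject ERP similarity.

Coherent averaging estimates the evoked response s(t) from M time-locked
epochs x_j(t) = s(t) + n_j(t) as the element-wise mean, attenuating zero-mean
background noise by 1/sqrt(M).  Averaged target waveforms are then compared
between subjects with two metrics: the angle cosine (dot(a, b)/|a||b|) with a
match threshold, and the Pearson correlation coefficient, whose descending
sort over candidate donors is the correlation-analysis-rank (CAR) ordering
used to assemble cross-subject training sets.

Waveforms enter both metrics the same way: the target-mean restricted to a
post-stimulus segment (default 0–800 ms), channels concatenated in channel
order.  The pre-stimulus baseline is excluded because baseline correction
leaves it near zero for every subject, which would inflate similarity.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .containers import EpochSet, ERPWaveform, SimilarityMatrix, SubjectRanking

DEFAULT_SEGMENT = (0.0, 800.0)


def coherent_average(epochs: EpochSet) -> ERPWaveform:
    """Element-wise mean over epochs, separately per class.

    Raises if either class is empty (an average of nothing is undefined and
    would silently poison every downstream similarity).
    """
    tgt = epochs.labels == 1
    ntg = epochs.labels == 0
    n_t = int(tgt.sum())
    n_n = int(ntg.sum())
    if n_t == 0:
        raise ValueError(f"no target epochs for subject {epochs.subject_id!r}")
    if n_n == 0:
        raise ValueError(f"no nontarget epochs for subject {epochs.subject_id!r}")
    return ERPWaveform(
        subject_id=epochs.subject_id,
        target_mean=epochs.data[tgt].mean(axis=0, dtype=np.float64),
        nontarget_mean=epochs.data[ntg].mean(axis=0, dtype=np.float64),
        n_target_epochs=n_t,
        n_nontarget_epochs=n_n,
        rate=epochs.rate,
        window=epochs.window,
        channel_names=list(epochs.channel_names),
    )


def vectorize_erp(
    erp: ERPWaveform, segment: tuple[float, float] = DEFAULT_SEGMENT
) -> np.ndarray:
    """Flatten the target mean over ``segment`` (ms, half-open), channels
    concatenated in ``channel_names`` order."""
    lo = erp.sample_index(segment[0])
    hi = erp.sample_index(segment[1])
    n = erp.target_mean.shape[1]
    if lo < 0 or hi > n or hi <= lo:
        raise ValueError(f"segment {segment} ms outside epoch window {erp.window}")
    return erp.target_mean[:, lo:hi].reshape(-1)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Angle cosine of two equal-length vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64).reshape(-1)
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient with sample (n−1) standard deviations.

    r = 1/(n−1) · Σ ((X_i − X̄)/s_X) · ((Y_i − Ȳ)/s_Y), bounded to [−1, 1].
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a correlation")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r = np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def _metric_fn(metric: str):
    if metric == "cosine":
        return cosine_similarity
    if metric == "pearson":
        return pearson_correlation
    raise ValueError(f"unknown metric {metric!r} (expected 'cosine' or 'pearson')")


def similarity_matrix(
    erps: Sequence[ERPWaveform],
    metric: str = "cosine",
    segment: tuple[float, float] = DEFAULT_SEGMENT,
) -> SimilarityMatrix:
    """Pairwise similarity between all subjects' vectorized target ERPs."""
    if len(erps) < 2:
        raise ValueError("need at least 2 subjects")
    fn = _metric_fn(metric)
    ids = [e.subject_id for e in erps]
    vecs = [vectorize_erp(e, segment) for e in erps]
    n = len(vecs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = fn(vecs[i], vecs[j])
            except ValueError as exc:
                raise ValueError(
                    f"similarity failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
    return SimilarityMatrix(
        subject_ids=ids,
        values=values,
        metric=metric,
        vectorization=f"target_mean[{segment[0]:g},{segment[1]:g})ms;channels-concat",
    )


def match_counts(
    erps: Sequence[ERPWaveform],
    threshold: float = 0.5,
    segment: tuple[float, float] = DEFAULT_SEGMENT,
) -> tuple[dict[str, int], np.ndarray]:
    """Per-subject number of *other* subjects whose angle cosine exceeds
    ``threshold`` (strict >; the diagonal is excluded).

    Returns the per-subject counts and the binarized match matrix.
    """
    sim = similarity_matrix(erps, metric="cosine", segment=segment)
    binary = (sim.values > threshold).astype(np.int8)
    np.fill_diagonal(binary, 0)
    counts = {sid: int(binary[i].sum()) for i, sid in enumerate(sim.subject_ids)}
    return counts, binary


def rank_donors(
    test_erp: ERPWaveform,
    donor_erps: Iterable[ERPWaveform],
    segment: tuple[float, float] = DEFAULT_SEGMENT,
) -> SubjectRanking:
    """CAR ordering: donors sorted by descending Pearson r of their vectorized
    target ERP with the test subject's; ties broken by ascending subject id.

    The test subject itself, if present among the donors, is skipped.
    """
    test_vec = vectorize_erp(test_erp, segment)
    scored: list[tuple[str, float]] = []
    for donor in donor_erps:
        if donor.subject_id == test_erp.subject_id:
            continue
        try:
            r = pearson_correlation(test_vec, vectorize_erp(donor, segment))
        except ValueError as exc:
            raise ValueError(
                f"correlation failed for donor {donor.subject_id!r}: {exc}"
            ) from exc
        scored.append((donor.subject_id, r))
    if not scored:
        raise ValueError("no donors to rank")
    scored.sort(key=lambda sr: (-sr[1], sr[0]))
    return SubjectRanking(
        test_subject=test_erp.subject_id, ranked_donors=scored, metric="pearson"
    )
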