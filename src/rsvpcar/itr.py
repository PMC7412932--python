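"""Symbol-selection accuracy and information transfer rate (ITR).

The Wolpaw-style ITR for an N-class speller with selection accuracy P and
selection time T (minutes):

    bits/selection = log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))
    ITR            = bits/selection / T

with P log2 P read as 0 at P in {0, 1} by continuity.  T is taken as pure
stimulus time — rounds × symbols × SOA — with no inter-trial pauses; any
other definition can be supplied directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet, ParadigmConfig
from .cross_subject_eval import FeatureConfig, TrainedClassifier, extract_features


@dataclass(frozen=True)
class ITRResult:
    n_classes: int
    accuracy: float  # P, in [1/N, 1]
    selection_minutes: float  # T
    bits_per_selection: float
    bits_per_minute: float


def selection_time(paradigm: ParadigmConfig) -> float:
    """Stimulus time of one symbol selection, in minutes:
    rounds_per_trial × n_symbols × (flash + off)."""
    ms = paradigm.rounds_per_trial * paradigm.n_symbols * paradigm.soa
    return ms / 1000.0 / 60.0


def compute_itr(n_classes: int, accuracy: float, minutes: float) -> ITRResult:
    """Evaluate the ITR formula exactly.

    Accuracy below chance (P < 1/N) is rejected: the formula turns negative
    there and a below-chance speller transmits no usable information.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if minutes <= 0:
        raise ValueError("selection time must be > 0")
    chance = 1.0 / n_classes
    if accuracy < chance - 1e-12:
        raise ValueError(
            f"accuracy {accuracy} below chance level 1/{n_classes}"
        )
    if accuracy > 1 + 1e-12:
        raise ValueError("accuracy cannot exceed 1")
    p = float(min(max(accuracy, chance), 1.0))
    bits = np.log2(n_classes)
    if 0 < p < 1:
        bits += p * np.log2(p) + (1 - p) * np.log2((1 - p) / (n_classes - 1))
    elif p < 1:  # p == 0 cannot occur (chance >= 1/N > 0); kept for clarity
        bits += np.log2(1.0 / (n_classes - 1))
    return ITRResult(
        n_classes=n_classes,
        accuracy=p,
        selection_minutes=minutes,
        bits_per_selection=float(bits),
        bits_per_minute=float(bits / minutes),
    )


def symbol_accuracy(
    epochs: EpochSet,
    clf: TrainedClassifier,
    cfg: FeatureConfig | None = None,
) -> float:
    """Fraction of trials whose target symbol is correctly selected.

    Per trial, each candidate symbol's classifier decision scores are summed
    over its ``rounds_per_trial`` presentations; the predicted symbol is the
    argmax (ties resolved to the alphabetically first symbol).
    """
    if epochs.block_idx is None or epochs.trial_idx is None:
        raise ValueError("epochs lack block/trial structure needed for selection")
    cfg = cfg or FeatureConfig(channels=tuple(epochs.channel_names))
    feats, _ = extract_features(epochs, cfg)
    scores = clf.decision_scores(feats)

    trials = {}
    for j in range(epochs.n_epochs):
        key = (int(epochs.block_idx[j]), int(epochs.trial_idx[j]))
        trials.setdefault(key, []).append(j)

    n_correct = 0
    n_trials = 0
    for key, idx in sorted(trials.items()):
        idx = np.asarray(idx)
        true_targets = set(epochs.symbols[idx][epochs.labels[idx] == 1])
        if len(true_targets) != 1:
            raise ValueError(f"trial {key} has no unique target symbol")
        true_sym = next(iter(true_targets))
        totals: dict[str, float] = {}
        for j in idx:
            totals[epochs.symbols[j]] = totals.get(epochs.symbols[j], 0.0) + scores[j]
        # argmax with alphabetical tie-break
        best = min(totals.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        n_correct += best == true_sym
        n_trials += 1
    return n_correct / n_trials
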