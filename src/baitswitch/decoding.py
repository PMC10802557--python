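"""Classifier harnesses for behavioral-state and sequence decoding.

Every decoding analysis follows one protocol: draw a uniform 75/25
train/test split (no stratification), fit the model, score held-out
accuracy as a percentage, repeat for many iterations, and test the mean
accuracy against chance (100/n_classes) with

    z = (mean accuracy - chance) / sd(accuracies)

declaring above-chance performance when z > 1.96.  Binary tasks
(behavioral state of the male partner; aggressive-vs-control sequence
class) use a decision tree; tasks with more than two classes (hour of the
recording; three-step sequence type) use a multiclass support-vector
machine with standardized features.

Two controls accompany the observed data: a *size-matched* dataset that
undersamples majority classes to the minority count, and *randomized*
data in which trigger times are redrawn uniformly (durations and roles
kept) to break the temporal link between triggers and interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import BehaviorEvent, Recording
from .sequences import ROLE_PAIRS, TriggeredSequence, trigger_events

__all__ = [
    "DecodingResult",
    "decode",
    "size_match",
    "randomize_triggers",
    "state_feature_table",
    "decode_sequence_class",
]


@dataclass
class DecodingResult:
    accuracies: np.ndarray  # per-iteration held-out accuracy, percent
    chance_pct: float
    model: str

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=0))

    @property
    def z(self) -> float:
        sd = self.sd
        diff = self.mean - self.chance_pct
        if sd > 0:
            return diff / sd
        return 0.0 if diff == 0 else float("inf") * (1 if diff > 0 else -1)

    @property
    def p(self) -> float:
        """One-sided normal p for accuracy above chance."""
        return float(stats.norm.sf(self.z)) if np.isfinite(self.z) else 0.0


def _make_model(model: str, seed: int):
    if model == "tree":
        # axis-aligned recursive partitioning, impurity splits, no depth cap
        return DecisionTreeClassifier(random_state=seed)
    if model == "multiclass_svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="linear", random_state=seed)
        )
    raise ValueError(f"unknown model {model!r}")


def _as_xy(features: pd.DataFrame, label_col: str = "label"):
    if label_col not in features.columns:
        raise ValueError(f"feature table needs a {label_col!r} column")
    y = features[label_col].to_numpy()
    X = features.drop(columns=[label_col])
    X = X.apply(pd.to_numeric).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X, y


def decode(
    features: pd.DataFrame,
    model: str = "tree",
    n_iterations: int = 1000,
    train_frac: float = 0.75,
    seed=None,
    label_col: str = "label",
) -> DecodingResult:
    """Repeated random-split decoding of the ``label`` column.

    ``features`` holds numeric predictor columns plus one categorical
    ``label`` column.  Each iteration draws an unstratified uniform split
    (75% train / 25% test by default), fits the model fresh, and records
    held-out accuracy in percent.  Chance is 100/n_classes.
    """
    X, y = _as_xy(features, label_col)
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 rows to decode")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train fraction leaves an empty split")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    model_seeds = master.integers(0, 2**31 - 1, size=n_iterations)
    acc = np.empty(n_iterations)
    for it in range(n_iterations):
        perm = master.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(np.unique(y[tr])) < 2:
            # degenerate training split: constant prediction
            pred = np.full(len(te), y[tr][0])
        else:
            clf = _make_model(model, int(model_seeds[it]))
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
        acc[it] = 100.0 * np.mean(pred == y[te])
    return DecodingResult(
        accuracies=acc, chance_pct=100.0 / len(classes), model=model
    )


def size_match(features: pd.DataFrame, seed=None, label_col: str = "label") -> pd.DataFrame:
    """Undersample majority classes to the minority class count."""
    counts = features[label_col].value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("size matching needs >= 2 non-empty classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, grp in features.groupby(label_col, sort=True):
        idx = rng.choice(len(grp), size=n_min, replace=False)
        parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts).sort_index().reset_index(drop=True)


def randomize_triggers(
    rec: Recording,
    trigger_class: str = "aggression",
    seed=None,
    max_tries: int = 10_000,
) -> Recording:
    """Redraw trigger start times uniformly; durations and roles kept.

    Disrupts the temporal relationship between triggers and social
    interactions while leaving the interactions untouched.  Triggers of
    the randomized class are re-placed without overlap among themselves
    (rejection sampling); all other events are unchanged.
    """
    rng = np.random.default_rng(seed)
    targets = trigger_events(rec, trigger_class)
    target_set = set(id(e) for e in targets)
    others = [e for e in rec.events if id(e) not in target_set]
    n_frames = rec.n_frames
    placed: list[tuple[int, int]] = []
    new_events = []
    for ev in targets:
        dur = ev.n_frames
        hi = n_frames - dur
        if hi < 0:
            raise ValueError("trigger longer than the recording")
        for _ in range(max_tries):
            s = int(rng.integers(0, hi + 1))
            e = s + dur - 1
            if all(e < ps or s > pe for ps, pe in placed):
                placed.append((s, e))
                break
        else:
            raise RuntimeError(
                f"could not place trigger of {dur} frames without overlap "
                f"after {max_tries} tries"
            )
        new_events.append(
            BehaviorEvent(
                behavior=ev.behavior,
                actor_id=ev.actor_id,
                recipient_id=ev.recipient_id,
                start_frame=s,
                end_frame=e,
            )
        )
    out = Recording(
        arena=rec.arena,
        mice=rec.mice,
        poses=rec.poses,
        events=sorted(others + new_events, key=lambda e: e.start_frame),
        metadata={**rec.metadata, "randomized_triggers": trigger_class},
    )
    return out


def state_feature_table(
    sequences: list[TriggeredSequence], include_state: bool = False
) -> pd.DataFrame:
    """Per-sequence latency/duration features labeled by male state.

    With ``include_state=True`` the binary state becomes a 0/1 predictor
    instead of the label (used when decoding sequence class or hour).
    """
    if not sequences:
        raise ValueError("no sequences")
    trigger_class = sequences[0].trigger_class
    first, _ = ROLE_PAIRS[trigger_class]
    df = pd.DataFrame(
        {
            "latency_s": [s.latency_s for s in sequences],
            "duration_s": [s.duration_s for s in sequences],
        }
    )
    state01 = np.array([int(s.male_state == first) for s in sequences])
    if include_state:
        df["male_state"] = state01
    else:
        df["label"] = np.where(state01 == 1, first, ROLE_PAIRS[trigger_class][1])
    return df


def decode_sequence_class(
    aggression_sequences: list[TriggeredSequence],
    control_sequences: list[TriggeredSequence],
    model: str = "tree",
    n_iterations: int = 1000,
    seed=None,
) -> DecodingResult:
    """Decode aggressive vs control sequence class from latency, duration
    and the (binary) behavioral state of the male partner; chance 50%."""
    fa = state_feature_table(aggression_sequences, include_state=True)
    fc = state_feature_table(control_sequences, include_state=True)
    fa["label"] = "aggression"
    fc["label"] = control_sequences[0].trigger_class
    features = pd.concat([fa, fc], ignore_index=True)
    return decode(features, model=model, n_iterations=n_iterations, seed=seed)
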