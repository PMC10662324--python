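"""Windowing, severity labels and subject-disjoint cross-validation splits.

Each >=300-s gameplay record contributes 28 overlapping 30-s windows
(10-s hop over the first 300 s); each window becomes one 304 x 30 x 1
normalized-scalogram tensor labeled by the subject's IAT severity band.
Fold assignment is at the subject level: all 3 x 28 windows of a subject
travel together, so no subject ever appears in both train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("normal", "mild", "moderate", "severe")
WINDOW_S = 30.0
HOP_S = 10.0
GAMEPLAY_USE_S = 300.0


def segment_windows(duration: float, window: float = WINDOW_S,
                    hop: float = HOP_S) -> list[float]:
    """Start offsets k*hop for k = 0..floor((duration - window)/hop)."""
    if duration < window:
        raise ValueError("record shorter than one window")
    k = int(np.floor((duration - window) / hop + 1e-9))
    return [i * hop for i in range(k + 1)]


@dataclass(frozen=True)
class SeverityLabel:
    severity: str
    iat_score: int

    @property
    def index(self) -> int:
        return CLASS_NAMES.index(self.severity)


def label_from_iat(score: int) -> SeverityLabel:
    """IAT bands: 0-30 normal, 31-50 mild, 51-80 moderate, 81-100 severe.

    (The IAT instrument itself is scored from 20; scores below 20 are
    accepted here since the normal band formally starts at 0.)
    """
    score = int(score)
    if not (0 <= score <= 100):
        raise ValueError("IAT score must be in 0..100")
    if score <= 30:
        cls = "normal"
    elif score <= 50:
        cls = "mild"
    elif score <= 80:
        cls = "moderate"
    else:
        cls = "severe"
    return SeverityLabel(severity=cls, iat_score=score)


@dataclass
class Dataset:
    """Stacked window tensors with per-window provenance."""

    X: np.ndarray                 # (n, 304, 30) normalized power ratios
    y: np.ndarray                 # (n,) class indices 0..3
    subject_ids: np.ndarray       # (n,) str
    episode: np.ndarray           # (n,) int, 1..3
    window_index: np.ndarray      # (n,) int, 0..27
    iat_scores: dict = field(default_factory=dict)   # subject -> score
    class_names: tuple = CLASS_NAMES

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def subject_class(self, subject_id: str) -> int:
        return int(self.y[self.subject_ids == subject_id][0])

    def manifest(self) -> dict:
        counts = {c: int((self.y == i).sum()) for i, c in enumerate(CLASS_NAMES)}
        return {
            "n_windows": len(self),
            "tensor_shape": [int(v) for v in self.X.shape[1:]] + [1],
            "values_per_window": int(np.prod(self.X.shape[1:])),
            "class_counts": counts,
            "subjects": [
                {"subject_id": s, "iat_score": self.iat_scores.get(s),
                 "class": CLASS_NAMES[self.subject_class(s)]}
                for s in self.subjects
            ],
        }


def build_dataset(cohort, method: str = "stft", detrend_order: int = 3,
                  min_episodes: int = 3) -> Dataset:
    """Run the full per-record pipeline over a synthetic cohort and assemble
    the labeled window tensors.

    Per subject: the baseline record is reduced to a per-frequency-bin mean
    PSD profile; each gameplay record (first 300 s) is cut into 28 windows
    whose scalograms are divided row-wise by that profile.  ``min_episodes``
    relaxes the three-episode requirement for small fixtures.
    """
    from .beats_hrv import record_to_tachogram
    from .timefreq import baseline_profile, compute_scalogram, normalize

    tensors, labels, subjects, episodes, widx = [], [], [], [], []
    iat_scores = {}
    for subj in cohort.subjects:
        baseline = [r for r in subj.records if r.phase == "baseline"]
        gameplay = sorted((r for r in subj.records if r.phase == "gameplay"),
                          key=lambda r: r.episode_index)
        if not baseline:
            raise ValueError(f"subject {subj.subject_id} has no baseline record")
        if len(gameplay) < min_episodes:
            raise ValueError(f"subject {subj.subject_id} has fewer than "
                             f"{min_episodes} gameplay records")
        label = label_from_iat(subj.iat_score)
        iat_scores[subj.subject_id] = subj.iat_score
        base_tach = record_to_tachogram(baseline[0], detrend_order=detrend_order)
        profile = baseline_profile(base_tach, method=method)
        for rec in gameplay:
            if rec.duration < GAMEPLAY_USE_S:
                raise ValueError(f"gameplay record of {subj.subject_id} shorter "
                                 f"than {GAMEPLAY_USE_S:.0f} s")
            tach = record_to_tachogram(rec, detrend_order=detrend_order)
            span = min(tach.values.size / tach.fs, GAMEPLAY_USE_S)
            nseg = int(WINDOW_S * tach.fs)
            for wi, off in enumerate(segment_windows(span)):
                i0 = int(round(off * tach.fs))
                seg = tach.values[i0:i0 + nseg]
                s = compute_scalogram(seg, method=method)
                tensors.append(normalize(s, profile).ratio.astype(np.float32))
                labels.append(label.index)
                subjects.append(subj.subject_id)
                episodes.append(rec.episode_index)
                widx.append(wi)
    return Dataset(X=np.stack(tensors), y=np.asarray(labels, dtype=int),
                   subject_ids=np.asarray(subjects, dtype=object),
                   episode=np.asarray(episodes, dtype=int),
                   window_index=np.asarray(widx, dtype=int),
                   iat_scores=iat_scores)


@dataclass
class CVSplit:
    folds: list                   # list of lists of subject_ids
    train_idx: list               # per fold, window indices
    test_idx: list

    def check_disjoint(self, dataset: Dataset) -> None:
        for f, (tr, te) in enumerate(zip(self.train_idx, self.test_idx)):
            tr_subj = set(map(str, dataset.subject_ids[tr]))
            te_subj = set(map(str, dataset.subject_ids[te]))
            if tr_subj & te_subj:
                raise ValueError(f"fold {f}: subjects leak between train and test")


def grouped_folds(dataset: Dataset, k: int = 10, seed: int = 0) -> CVSplit:
    """Deal subjects into ``k`` folds, class-balanced and subject-disjoint.

    Subjects are shuffled within class (seeded) and dealt class by class with
    a single round-robin pointer over the folds, so per-class counts and
    totals differ by at most one across folds.
    """
    subjects = dataset.subjects
    if len(subjects) < k:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for s in subjects:
        by_class.setdefault(dataset.subject_class(s), []).append(s)
    folds: list[list[str]] = [[] for _ in range(k)]
    ptr = 0
    for cls in sorted(by_class):
        members = list(by_class[cls])
        rng.shuffle(members)
        for s in members:
            folds[ptr % k].append(s)
            ptr += 1
    train_idx, test_idx = [], []
    sid = dataset.subject_ids.astype(str)
    for f in range(k):
        te_mask = np.isin(sid, folds[f])
        test_idx.append(np.nonzero(te_mask)[0])
        train_idx.append(np.nonzero(~te_mask)[0])
    split = CVSplit(folds=folds, train_idx=train_idx, test_idx=test_idx)
    split.check_disjoint(dataset)
    return split
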