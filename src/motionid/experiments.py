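"""Train/test split construction and the per-target evaluation loop.

Four experiment families probe how training-data characteristics affect
per-user authentication:

* **Decoy protocol** — four users are held out of every training set as
  unseen negatives ("decoys", simulating unknown household members sharing a
  device) but appear in the test set.  Each remaining user serves as the
  target of their own one-vs-rest model, trained on one random laying minute
  and one random sitting minute from every non-decoy user, and tested on the
  target's and the decoys' last three sitting minutes.
* **Length / proximity sweeps** — over a 12-minute training timeline (the
  last 9 laying minutes followed by the first 3 sitting minutes), training
  either grows forward from the start of the timeline (its trailing edge
  approaching the test block as it grows) or is trimmed from the start while
  staying adjacent to the test block.  The test set is always the last two
  sitting minutes.
* **Position cross-over** — two-minute training blocks of laying, sitting or
  mixed (1 + 1) data against two-minute laying or sitting test blocks, with a
  sliding offset enumerating every valid consecutive training block.

Decoys are chosen once per cohort seed and held constant across analyses.
Every split asserts decoy purity (no decoy window in any training matrix) and
train/test time-disjointness for the same user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import feature_matrix, raw_sequence_tensor
from .metrics import MetricsSet, compute_metrics
from .models import (
    CLASSICAL_KINDS,
    HyperparameterGrid,
    TransformerConfig,
    fit_classical,
    fit_swipeformer,
    predict,
)
from .sensor_io import SensorRecording, fit_minmax, segment_windows
from .synthetic import ProtocolSpec

__all__ = [
    "DEFAULT_N_DECOYS",
    "Selection",
    "ExperimentSpec",
    "ExperimentResult",
    "CohortData",
    "pick_decoys",
    "build_rq1_split",
    "build_rq1_experiments",
    "build_length_sweep",
    "sweep_timeline",
    "position_split_candidates",
    "build_position_split",
    "run_experiment",
]

DEFAULT_N_DECOYS = 4

POSITION_TRAIN_KINDS = ("laying2", "sitting2", "mixed1+1")
POSITION_TEST_KINDS = ("laying2", "sitting2")


@dataclass(frozen=True)
class Selection:
    """One user's contribution to a split: whole protocol minutes (1-based)."""

    user_id: str
    minutes: tuple[int, ...]


@dataclass(frozen=True)
class ExperimentSpec:
    """A reproducible train/test split recipe for one target's model."""

    rq_id: str
    target_user_id: str
    decoy_user_ids: tuple[str, ...]
    train_selection: tuple[Selection, ...]
    test_selection: tuple[Selection, ...]
    seed: int
    gap_to_test_min: float | None = None
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        train_users = {s.user_id for s in self.train_selection}
        test_users = {s.user_id for s in self.test_selection}
        if set(self.decoy_user_ids) & train_users:
            raise ValueError("decoys must never appear in the training selection")
        if self.target_user_id not in train_users or self.target_user_id not in test_users:
            raise ValueError("target must appear in both train and test selections")
        train_minutes = {
            (s.user_id, m) for s in self.train_selection for m in s.minutes
        }
        test_minutes = {(s.user_id, m) for s in self.test_selection for m in s.minutes}
        if train_minutes & test_minutes:
            raise ValueError("train and test minutes overlap for some user")

    def validate_protocol(self, protocol: ProtocolSpec) -> None:
        for sel in self.train_selection + self.test_selection:
            for m in sel.minutes:
                if not 1 <= m <= protocol.total_minutes:
                    raise ValueError(
                        f"minute {m} outside protocol bounds 1..{protocol.total_minutes}"
                    )

    def to_dict(self) -> dict:
        return {
            "rq_id": self.rq_id,
            "target_user_id": self.target_user_id,
            "decoy_user_ids": list(self.decoy_user_ids),
            "train_selection": [
                {"user_id": s.user_id, "minutes": list(s.minutes)}
                for s in self.train_selection
            ],
            "test_selection": [
                {"user_id": s.user_id, "minutes": list(s.minutes)}
                for s in self.test_selection
            ],
            "seed": self.seed,
            "gap_to_test_min": self.gap_to_test_min,
            "meta": dict(self.meta),
        }


def pick_decoys(
    user_ids: Sequence[str], seed: int, n_decoys: int = DEFAULT_N_DECOYS
) -> tuple[str, ...]:
    """Choose the cohort's decoys once per seed; constant across analyses."""
    users = sorted(user_ids)
    if len(users) - n_decoys < 2:
        raise ValueError(
            f"cohort of {len(users)} users cannot spare {n_decoys} decoys and "
            "still train one-vs-rest models"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed & 0x7FFFFFFF, 41)))
    return tuple(sorted(rng.choice(users, size=n_decoys, replace=False)))


def _rq1_test_minutes(protocol: ProtocolSpec) -> tuple[int, ...]:
    """The last 3 sitting minutes."""
    sitting = protocol.sitting_minute_indices
    if len(sitting) < 3:
        raise ValueError("protocol too short: need >= 3 sitting minutes for testing")
    return sitting[-3:]


def build_rq1_split(
    user_ids: Sequence[str],
    target: str,
    seed: int,
    protocol: ProtocolSpec | None = None,
    n_decoys: int = DEFAULT_N_DECOYS,
) -> ExperimentSpec:
    """The decoy-protocol split for one target.

    Training: one seeded-random laying minute and one seeded-random sitting
    minute from each non-decoy user.  The target's random sitting minute is
    drawn from the sitting minutes outside the test block so train and test
    never overlap in time for the same user.  Testing: the target's and the
    four decoys' last three sitting minutes.
    """
    protocol = protocol or ProtocolSpec()
    decoys = pick_decoys(user_ids, seed, n_decoys)
    if target in decoys:
        raise ValueError(f"target {target!r} is a decoy for this cohort seed")
    if target not in user_ids:
        raise ValueError(f"target {target!r} not in cohort")
    trainers = [u for u in sorted(user_ids) if u not in decoys]
    test_minutes = _rq1_test_minutes(protocol)
    laying = protocol.laying_minute_indices
    sitting = protocol.sitting_minute_indices
    target_sitting_pool = [m for m in sitting if m not in test_minutes]
    if not target_sitting_pool:
        raise ValueError("protocol too short: no sitting minute left for training")
    train_sel = []
    for i, user in enumerate(trainers):
        rng = np.random.default_rng(
            np.random.SeedSequence((seed & 0x7FFFFFFF, 43, i, _stable_tag(target)))
        )
        lay_minute = int(rng.choice(laying))
        pool = target_sitting_pool if user == target else list(sitting)
        sit_minute = int(rng.choice(pool))
        train_sel.append(Selection(user_id=user, minutes=(lay_minute, sit_minute)))
    test_sel = [
        Selection(user_id=u, minutes=test_minutes) for u in sorted({target, *decoys})
    ]
    return ExperimentSpec(
        rq_id="rq1",
        target_user_id=target,
        decoy_user_ids=decoys,
        train_selection=tuple(train_sel),
        test_selection=tuple(test_sel),
        seed=seed,
    )


def _stable_tag(text: str) -> int:
    """A small stable integer from a string (for seed fan-out)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def build_rq1_experiments(
    user_ids: Sequence[str],
    seed: int,
    protocol: ProtocolSpec | None = None,
    n_decoys: int = DEFAULT_N_DECOYS,
) -> list[ExperimentSpec]:
    """One decoy-protocol spec per eligible (non-decoy) target."""
    decoys = pick_decoys(user_ids, seed, n_decoys)
    return [
        build_rq1_split(user_ids, target, seed, protocol, n_decoys)
        for target in sorted(user_ids)
        if target not in decoys
    ]


def sweep_timeline(
    protocol: ProtocolSpec | None = None, dropped_laying_minute: int | None = None
) -> tuple[int, ...]:
    """The training timeline for the length/proximity sweeps.

    For the default 10 + 5 protocol this is 12 minutes: the last 9 laying
    minutes plus the first 3 sitting minutes, with the last 2 sitting minutes
    reserved for testing.  Which laying minute to drop is configurable; by
    default the first (warm-up) minute is excluded.
    """
    protocol = protocol or ProtocolSpec()
    laying = list(protocol.laying_minute_indices)
    sitting = list(protocol.sitting_minute_indices)
    if len(sitting) < 3:
        raise ValueError("protocol too short: need >= 3 sitting minutes")
    dropped = dropped_laying_minute if dropped_laying_minute is not None else laying[0]
    if dropped not in laying:
        raise ValueError(f"dropped_laying_minute {dropped} is not a laying minute")
    timeline = [m for m in laying if m != dropped] + sitting[:-2]
    return tuple(timeline)


def build_length_sweep(
    user_ids: Sequence[str],
    target: str,
    direction: str,
    minutes: int,
    seed: int,
    protocol: ProtocolSpec | None = None,
    n_decoys: int = DEFAULT_N_DECOYS,
    dropped_laying_minute: int | None = None,
) -> ExperimentSpec:
    """A training-length/proximity split for one target.

    ``forward_from_start`` with m minutes trains on timeline minutes 1..m, so
    the trailing edge moves toward the test block as m grows (gap-to-test =
    timeline length - m).  ``backward_trim`` trains on the last m timeline
    minutes, keeping the trailing edge adjacent to the test block (gap 0).
    The test set is always the last two sitting minutes of the target and the
    decoys.
    """
    protocol = protocol or ProtocolSpec()
    if direction not in ("forward_from_start", "backward_trim"):
        raise ValueError(
            f"direction must be forward_from_start or backward_trim, got {direction!r}"
        )
    timeline = sweep_timeline(protocol, dropped_laying_minute)
    if not 1 <= minutes <= len(timeline):
        raise ValueError(f"minutes must be in 1..{len(timeline)}, got {minutes}")
    decoys = pick_decoys(user_ids, seed, n_decoys)
    if target in decoys or target not in user_ids:
        raise ValueError(f"target {target!r} is not an eligible (non-decoy) user")
    if direction == "forward_from_start":
        chosen = timeline[:minutes]
        gap = float(len(timeline) - minutes)
        rq_id = "rq2_forward"
    else:
        chosen = timeline[-minutes:]
        gap = 0.0
        rq_id = "rq3_backward"
    trainers = [u for u in sorted(user_ids) if u not in decoys]
    test_minutes = protocol.sitting_minute_indices[-2:]
    train_sel = tuple(Selection(user_id=u, minutes=chosen) for u in trainers)
    test_sel = tuple(
        Selection(user_id=u, minutes=test_minutes) for u in sorted({target, *decoys})
    )
    return ExperimentSpec(
        rq_id=rq_id,
        target_user_id=target,
        decoy_user_ids=decoys,
        train_selection=train_sel,
        test_selection=test_sel,
        seed=seed,
        gap_to_test_min=gap,
        meta={"direction": direction, "train_minutes": minutes},
    )


def _position_test_minutes(test_kind: str, protocol: ProtocolSpec) -> tuple[int, ...]:
    if test_kind == "laying2":
        return protocol.laying_minute_indices[-2:]
    if test_kind == "sitting2":
        return protocol.sitting_minute_indices[-2:]
    raise ValueError(f"test kind must be one of {POSITION_TEST_KINDS}, got {test_kind!r}")


def position_split_candidates(
    train_kind: str, test_kind: str, protocol: ProtocolSpec | None = None
) -> list[tuple[int, ...]]:
    """Every valid training-minute block for a position cross-over analysis.

    Same-position blocks are consecutive 2-minute runs of that position not
    overlapping the test block (7 laying offsets against a laying test from
    the 8 remaining laying minutes; 2 sitting offsets against a sitting test
    from the 3 remaining sitting minutes).  Mixed blocks pair one laying and
    one sitting minute.
    """
    protocol = protocol or ProtocolSpec()
    test_minutes = set(_position_test_minutes(test_kind, protocol))
    laying_pool = [m for m in protocol.laying_minute_indices if m not in test_minutes]
    sitting_pool = [m for m in protocol.sitting_minute_indices if m not in test_minutes]
    if train_kind == "laying2":
        pool = laying_pool
    elif train_kind == "sitting2":
        pool = sitting_pool
    elif train_kind == "mixed1+1":
        return [(lay, sit) for lay in laying_pool for sit in sitting_pool]
    else:
        raise ValueError(
            f"train kind must be one of {POSITION_TRAIN_KINDS}, got {train_kind!r}"
        )
    return [
        (a, b) for a, b in zip(pool[:-1], pool[1:]) if b == a + 1
    ]


def build_position_split(
    user_ids: Sequence[str],
    target: str,
    train_kind: str,
    test_kind: str,
    offset: int,
    seed: int,
    protocol: ProtocolSpec | None = None,
    n_decoys: int = DEFAULT_N_DECOYS,
) -> ExperimentSpec:
    """One position cross-over split; ``offset`` indexes the sliding block."""
    protocol = protocol or ProtocolSpec()
    candidates = position_split_candidates(train_kind, test_kind, protocol)
    if not candidates:
        raise ValueError(
            f"no valid training block for train={train_kind!r} test={test_kind!r}"
        )
    if not 0 <= offset < len(candidates):
        raise ValueError(
            f"offset {offset} out of range: {len(candidates)} candidate block(s) "
            f"for train={train_kind!r} test={test_kind!r}"
        )
    decoys = pick_decoys(user_ids, seed, n_decoys)
    if target in decoys or target not in user_ids:
        raise ValueError(f"target {target!r} is not an eligible (non-decoy) user")
    chosen = candidates[offset]
    test_minutes = _position_test_minutes(test_kind, protocol)
    trainers = [u for u in sorted(user_ids) if u not in decoys]
    # Proximity bookkeeping: minutes between the end of the nearest
    # same-position training minute and the start of the test block.
    same_position_minutes = [
        m
        for m in chosen
        if (m in protocol.laying_minute_indices) == (test_kind == "laying2")
    ]
    gap = (
        float(test_minutes[0] - max(same_position_minutes) - 1)
        if same_position_minutes
        else None
    )
    return ExperimentSpec(
        rq_id=f"rq4_{train_kind}x{test_kind}",
        target_user_id=target,
        decoy_user_ids=decoys,
        train_selection=tuple(Selection(user_id=u, minutes=chosen) for u in trainers),
        test_selection=tuple(
            Selection(user_id=u, minutes=test_minutes) for u in sorted({target, *decoys})
        ),
        seed=seed,
        gap_to_test_min=gap,
        meta={"train_kind": train_kind, "test_kind": test_kind, "offset": offset},
    )


class CohortData:
    """Windowed, feature-extracted cohort recordings indexed by (user, minute).

    Holds the 56-feature matrix for every 1-second window of every user and,
    optionally, the raw 6-channel sequences the transformer consumes.  Split
    recipes select rows from this container, so features are computed once
    per cohort regardless of how many experiments run on it.
    """

    def __init__(
        self,
        protocol: ProtocolSpec,
        features: np.ndarray,
        window_user: np.ndarray,
        window_minute: np.ndarray,
        window_position: np.ndarray,
        window_id: np.ndarray,
        sequences: np.ndarray | None = None,
    ):
        self.protocol = protocol
        self.features = features
        self.window_user = window_user
        self.window_minute = window_minute
        self.window_position = window_position
        self.window_id = window_id
        self.sequences = sequences

    @property
    def user_ids(self) -> list[str]:
        return sorted(set(self.window_user.tolist()))

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[SensorRecording],
        protocol: ProtocolSpec | None = None,
        include_sequences: bool = False,
    ) -> "CohortData":
        protocol = protocol or ProtocolSpec()
        feats, users, minutes, positions, ids = [], [], [], [], []
        seqs = []
        for rec in recordings:
            windows = segment_windows(rec)
            if not windows:
                continue
            feats.append(feature_matrix(windows))
            if include_sequences:
                seqs.append(raw_sequence_tensor(windows, protocol.sample_rate_hz))
            for sec, w in enumerate(windows):
                users.append(w.user_id)
                minutes.append(sec // 60 + 1)  # 1-based protocol minute
                positions.append(w.position)
                ids.append(f"{w.user_id}:{sec:04d}")
        if not feats:
            raise ValueError("no recordings long enough to window")
        return cls(
            protocol=protocol,
            features=np.concatenate(feats, axis=0),
            window_user=np.array(users),
            window_minute=np.array(minutes, dtype=int),
            window_position=np.array(positions),
            window_id=np.array(ids),
            sequences=np.concatenate(seqs, axis=0) if include_sequences else None,
        )

    def select(self, selections: Sequence[Selection]) -> np.ndarray:
        """Row indices of all windows covered by the given selections."""
        idx: list[np.ndarray] = []
        for sel in selections:
            mask = (self.window_user == sel.user_id) & np.isin(
                self.window_minute, sel.minutes
            )
            rows = np.flatnonzero(mask)
            if len(rows) == 0:
                raise ValueError(
                    f"cohort has no windows for user {sel.user_id!r} "
                    f"minutes {sel.minutes}"
                )
            idx.append(rows)
        return np.sort(np.concatenate(idx))


@dataclass
class ExperimentResult:
    """One (spec, model) evaluation with per-window predictions."""

    spec: ExperimentSpec
    model_kind: str
    metrics: MetricsSet
    predictions: pd.DataFrame  # window_id, user_id, truth, score, decision
    chosen_hyperparameters: dict[str, Any]
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        hp = {
            k: (str(v) if not isinstance(v, (int, float, str, bool)) else v)
            for k, v in self.chosen_hyperparameters.items()
        }
        return {
            "spec": self.spec.to_dict(),
            "model_kind": self.model_kind,
            "metrics": self.metrics.to_dict(),
            "chosen_hyperparameters": hp,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "predictions": {
                "window_id": self.predictions["window_id"].tolist(),
                "user_id": self.predictions["user_id"].tolist(),
                "truth": [int(v) for v in self.predictions["truth"]],
                "score": [float(v) for v in self.predictions["score"]],
                "decision": [int(v) for v in self.predictions["decision"]],
            },
        }


def run_experiment(
    spec: ExperimentSpec,
    model_kind: str,
    cohort: CohortData,
    grid: HyperparameterGrid | None = None,
    transformer_config: TransformerConfig | None = None,
) -> ExperimentResult:
    """Execute one split end-to-end: normalize, fit, predict, score.

    Min-max normalization is fit on the training windows only.  Decoy purity
    and train/test window disjointness are asserted on every run.
    """
    spec.validate_protocol(cohort.protocol)
    train_idx = cohort.select(spec.train_selection)
    test_idx = cohort.select(spec.test_selection)

    train_users = set(cohort.window_user[train_idx].tolist())
    if train_users & set(spec.decoy_user_ids):
        raise AssertionError("decoy window found in the training matrix")
    overlap = set(cohort.window_id[train_idx]) & set(cohort.window_id[test_idx])
    if overlap:
        raise AssertionError(f"train/test windows overlap: {sorted(overlap)[:5]}")

    y_train = (cohort.window_user[train_idx] == spec.target_user_id).astype(int)
    y_test = (cohort.window_user[test_idx] == spec.target_user_id).astype(int)
    train_ids = tuple(cohort.window_id[train_idx])

    if model_kind in CLASSICAL_KINDS:
        scaler = fit_minmax(cohort.features[train_idx])
        X_train = scaler.transform(cohort.features[train_idx])
        X_test = scaler.transform(cohort.features[test_idx])
        model = fit_classical(
            model_kind,
            X_train,
            y_train,
            grid=grid,
            seed=spec.seed,
            target_user_id=spec.target_user_id,
            train_window_ids=train_ids,
        )
        decisions, scores = predict(model, X_test)
    elif model_kind == "swipeformer":
        if cohort.sequences is None:
            raise ValueError(
                "cohort was built without raw sequences; rebuild with "
                "include_sequences=True to run the transformer"
            )
        cfg = transformer_config or TransformerConfig(
            sequence_length=cohort.protocol.sample_rate_hz, seed=spec.seed
        )
        model = fit_swipeformer(
            cohort.sequences[train_idx],
            y_train,
            config=cfg,
            target_user_id=spec.target_user_id,
            train_window_ids=train_ids,
        )
        decisions, scores = predict(model, cohort.sequences[test_idx])
    else:
        raise ValueError(f"unknown model kind: {model_kind!r}")

    predictions = pd.DataFrame(
        {
            "window_id": cohort.window_id[test_idx],
            "user_id": cohort.window_user[test_idx],
            "truth": y_test,
            "score": scores,
            "decision": decisions.astype(int),
        }
    )
    return ExperimentResult(
        spec=spec,
        model_kind=model_kind,
        metrics=compute_metrics(y_test, decisions),
        predictions=predictions,
        chosen_hyperparameters=dict(model.chosen_hyperparameters),
        n_train=int(len(train_idx)),
        n_test=int(len(test_idx)),
    )
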