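"""Multiview bag-of-key-poses model.

Training sequences of radial pose descriptors are clustered per
(view, action-class) group with K-means; the K cluster centres of each of
the M x R groups become *key poses*, labelled with their group.  Every
training frame is then matched to its nearest key pose (Euclidean
distance), which yields

* a discriminative weight per key pose — the fraction of its matches
  coming from its own action class,
* the model-wide ``average_distance`` — the mean frame-to-nearest-key-pose
  distance observed during training, and
* one *sequence of key poses* per training sequence, i.e. the original
  frame sequence rewritten as nearest-neighbour key-pose indices.

The resulting model is a shared dictionary over all camera views (model
fusion): a single bag holds view-labelled key poses, so recognition does
not need to know which physical camera produced a test stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .features import RadialFeatureConfig

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

AVERAGE_DISTANCE_MODES = ("assignments", "pairwise")


@dataclass
class LabeledFeatureSequence:
    """One view-stream of one video sequence, as per-frame pose features."""

    frames: np.ndarray  # (T, S) float array
    action_class: str
    view: str
    actor: str
    sequence_id: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (T, S) array")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class KeyPose:
    feature: np.ndarray
    action_class: str
    view: str
    weight: float = 0.0
    matches: int = 0
    assignments: int = 0

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=float)


@dataclass
class BagOfKeyPoses:
    """K x M x R key-pose dictionary plus the trained average distance."""

    key_poses: list[KeyPose]
    K: int
    M: int
    R: int
    average_distance: float = 0.0

    def __len__(self) -> int:
        return len(self.key_poses)

    @property
    def feature_matrix(self) -> np.ndarray:
        return np.stack([kp.feature for kp in self.key_poses])

    @property
    def weights(self) -> np.ndarray:
        return np.array([kp.weight for kp in self.key_poses])


@dataclass
class KeyPoseSequence:
    """A sequence rewritten as indices into the bag of key poses."""

    indices: np.ndarray
    action_class: str
    view: str
    actor: str
    sequence_id: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ActionModel:
    """A trained bag of key poses plus the converted training sequences."""

    bag: BagOfKeyPoses
    sequences: list[KeyPoseSequence]
    feature_config: RadialFeatureConfig
    K: int
    seed: int
    average_distance_mode: str = "assignments"


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def learn_key_poses(
    train: list[LabeledFeatureSequence],
    K: int,
    seed: int = 0,
    n_init: int = 10,
) -> BagOfKeyPoses:
    """Cluster each (view, class) group of training frames into K key poses.

    K-means with Euclidean distance runs separately per group
    (seeded k-means++ initialisation, ``n_init`` restarts, best inertia
    kept).  If a group holds fewer than K frames, K is clamped to the frame
    count for that group, so the bag can be smaller than K x M x R on very
    scarce data.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if not train:
        raise ValueError("empty training set")

    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for seq in train:
        groups.setdefault((seq.view, seq.action_class), []).append(seq.frames)

    views = sorted({v for v, _ in groups})
    classes = sorted({c for _, c in groups})

    key_poses: list[KeyPose] = []
    for view, cls in sorted(groups):
        X = np.concatenate(groups[(view, cls)])
        k = K
        if len(X) < K:
            logger.warning(
                "group (view=%s, class=%s) has %d frames < K=%d; clamping",
                view, cls, len(X), K,
            )
            k = len(X)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        for center in km.cluster_centers_:
            key_poses.append(KeyPose(feature=center, action_class=cls, view=view))
    return BagOfKeyPoses(key_poses=key_poses, K=K, M=len(views), R=len(classes))


def nearest_key_pose(x, bag: BagOfKeyPoses) -> tuple[int, float]:
    """Index and Euclidean distance of the nearest key pose to feature ``x``.

    Ties are broken toward the lowest key-pose index.
    """
    if len(bag) == 0:
        raise ValueError("empty bag of key poses")
    dists = np.linalg.norm(bag.feature_matrix - np.asarray(x, dtype=float), axis=1)
    idx = int(np.argmin(dists))
    return idx, float(dists[idx])


def _nearest_indices(frames: np.ndarray, bag: BagOfKeyPoses):
    dists = cdist(frames, bag.feature_matrix)
    idx = dists.argmin(axis=1)
    return idx, dists[np.arange(len(frames)), idx]


def compute_weights(
    bag: BagOfKeyPoses, train: list[LabeledFeatureSequence]
) -> BagOfKeyPoses:
    """Assign discriminative weights w = matches/assignments to the bag.

    Every training frame is matched with its nearest key pose;
    ``assignments`` counts how often a key pose was selected, ``matches``
    how often the selecting frame belonged to the key pose's own action
    class.  Key poses never selected keep w = 0 (they stay in the bag and
    can still be nearest neighbours at test time).
    """
    matches = np.zeros(len(bag), dtype=int)
    assignments = np.zeros(len(bag), dtype=int)
    for seq in train:
        idx, _ = _nearest_indices(seq.frames, bag)
        for i in idx:
            assignments[i] += 1
            if bag.key_poses[i].action_class == seq.action_class:
                matches[i] += 1
    for i, kp in enumerate(bag.key_poses):
        kp.matches = int(matches[i])
        kp.assignments = int(assignments[i])
        kp.weight = float(matches[i] / assignments[i]) if assignments[i] else 0.0
    return bag


def to_key_pose_sequence(
    seq: LabeledFeatureSequence, bag: BagOfKeyPoses
) -> KeyPoseSequence:
    """Rewrite a frame sequence as its nearest-neighbour key-pose indices."""
    if len(bag) == 0:
        raise ValueError("empty bag of key poses")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    idx, _ = _nearest_indices(seq.frames, bag)
    return KeyPoseSequence(
        indices=idx,
        action_class=seq.action_class,
        view=seq.view,
        actor=seq.actor,
        sequence_id=seq.sequence_id,
    )


def compute_average_distance(
    bag: BagOfKeyPoses,
    train: list[LabeledFeatureSequence],
    mode: str = "assignments",
) -> float:
    """Average key-pose distance observed during training.

    ``assignments`` (default): mean of the nearest-key-pose distances of
    all training frames — the distances actually computed while converting
    the training set.  ``pairwise``: mean pairwise Euclidean distance
    among the key poses themselves.
    """
    if mode not in AVERAGE_DISTANCE_MODES:
        raise ValueError(f"mode must be one of {AVERAGE_DISTANCE_MODES}")
    if mode == "pairwise":
        F = bag.feature_matrix
        if len(F) < 2:
            return 0.0
        D = cdist(F, F)
        iu = np.triu_indices(len(F), k=1)
        return float(D[iu].mean())
    if not train:
        raise ValueError("no training frames to average over")
    dists = []
    for seq in train:
        _, d = _nearest_indices(seq.frames, bag)
        dists.append(d)
    return float(np.concatenate(dists).mean())


def train_model(
    train: list[LabeledFeatureSequence],
    feature_config: RadialFeatureConfig,
    K: int,
    seed: int = 0,
    average_distance_mode: str = "assignments",
    n_init: int = 10,
) -> ActionModel:
    """Full training stage: bag, weights, average distance, sequences."""
    bag = learn_key_poses(train, K, seed=seed, n_init=n_init)
    compute_weights(bag, train)
    bag.average_distance = compute_average_distance(
        bag, train, mode=average_distance_mode
    )
    sequences = [to_key_pose_sequence(seq, bag) for seq in train]
    return ActionModel(
        bag=bag,
        sequences=sequences,
        feature_config=feature_config,
        K=K,
        seed=seed,
        average_distance_mode=average_distance_mode,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: ActionModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "S": model.feature_config.S,
            "summary": model.feature_config.summary,
            "K": model.K,
            "seed": model.seed,
            "average_distance_mode": model.average_distance_mode,
        },
        "bag": {
            "K": model.bag.K,
            "M": model.bag.M,
            "R": model.bag.R,
            "average_distance": model.bag.average_distance,
            "key_poses": [
                {
                    "feature": kp.feature.tolist(),
                    "action_class": kp.action_class,
                    "view": kp.view,
                    "weight": kp.weight,
                    "matches": kp.matches,
                    "assignments": kp.assignments,
                }
                for kp in model.bag.key_poses
            ],
        },
        "sequences": [
            {
                "indices": seq.indices.tolist(),
                "action_class": seq.action_class,
                "view": seq.view,
                "actor": seq.actor,
                "sequence_id": seq.sequence_id,
            }
            for seq in model.sequences
        ],
    }


def model_from_dict(data: dict) -> ActionModel:
    if data.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {data.get('format_version')!r}"
        )
    cfg = data["config"]
    bag_d = data["bag"]
    bag = BagOfKeyPoses(
        key_poses=[
            KeyPose(
                feature=np.array(kp["feature"], dtype=float),
                action_class=kp["action_class"],
                view=kp["view"],
                weight=kp["weight"],
                matches=kp["matches"],
                assignments=kp["assignments"],
            )
            for kp in bag_d["key_poses"]
        ],
        K=bag_d["K"],
        M=bag_d["M"],
        R=bag_d["R"],
        average_distance=bag_d["average_distance"],
    )
    sequences = [
        KeyPoseSequence(
            indices=np.array(s["indices"], dtype=int),
            action_class=s["action_class"],
            view=s["view"],
            actor=s["actor"],
            sequence_id=s["sequence_id"],
        )
        for s in data["sequences"]
    ]
    return ActionModel(
        bag=bag,
        sequences=sequences,
        feature_config=RadialFeatureConfig(S=cfg["S"], summary=cfg["summary"]),
        K=cfg["K"],
        seed=cfg["seed"],
        average_distance_mode=cfg["average_distance_mode"],
    )


def save_model(model: ActionModel, path) -> None:
    """Write the model as a versioned JSON file (floats round-trip exactly)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> ActionModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
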