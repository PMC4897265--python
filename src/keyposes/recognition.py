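"""Sequence matching and recognition with relevance-weighted DTW.

A test stream is converted to a sequence of key poses with the trained
bag and compared by dynamic time warping (DTW) against every stored
training key-pose sequence.  The pairwise cost between two key poses is
the Euclidean distance between their features, adjusted by the
*relevance* of the match:

    d(i, j) = e(i, j) + z * |dev(i, j)| * w_i * w_j
    dev(i, j) = e(i, j) - average_distance

where w_i, w_j are the discriminative weights of the two key poses and z
in {-1, +1} rewards or penalises the match depending on the weight
pairing (discriminative vs. ambiguous) and the sign of the deviation.
Matches of two discriminative key poses that are closer than average are
rewarded (z = -1); discriminative/ambiguous pairings are penalised
(z = +1); pairs of ambiguous key poses barely matter either way (z = -1
on a small |dev|-scaled term).  Pair costs can therefore be negative;
accumulated DTW distances are comparable because every match uses the
same scheme.

The label of the training sequence with the globally lowest DTW distance
— across every available camera view — is the prediction (*best view*
decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model import ActionModel, BagOfKeyPoses, KeyPose, KeyPoseSequence, _nearest_indices


@dataclass(frozen=True)
class MatchParams:
    """Thresholds and switches of the relevance-weighted key-pose cost.

    ``ambiguous_threshold`` / ``discriminative_threshold`` split the weight
    range: w < 0.1 is an *ambiguous* key pose, w > 0.9 a *discriminative*
    one.  With ``use_relevance`` off, the cost is the plain Euclidean
    distance.  ``signed_relevance`` switches the relevance magnitude from
    |dev| * w_i * w_j to the signed dev * w_i * w_j variant.
    """

    ambiguous_threshold: float = 0.1
    discriminative_threshold: float = 0.9
    use_relevance: bool = True
    signed_relevance: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.ambiguous_threshold < self.discriminative_threshold <= 1):
            raise ValueError(
                "thresholds must satisfy 0 <= ambiguous < discriminative <= 1"
            )


@dataclass
class RecognitionResult:
    predicted_class: str
    best_view: str
    best_training_sequence_id: str
    distance: float
    #: per test view: (best distance, predicted label, training sequence id)
    per_view_distances: dict[str, tuple[float, str, str]]


def select_z(w_i: float, w_j: float, dev: float, params: MatchParams = MatchParams()) -> int:
    """Sign of the relevance adjustment for one key-pose pairing.

    Both discriminative: follow the sign of the deviation (reward
    below-average distances, penalise above-average ones).  Both
    ambiguous: -1.  One discriminative and one ambiguous: +1.  Any other
    pairing falls back to the sign-of-deviation rule.  dev = 0 counts as
    below average (z = -1).
    """
    lo, hi = params.ambiguous_threshold, params.discriminative_threshold
    disc_i, disc_j = w_i > hi, w_j > hi
    amb_i, amb_j = w_i < lo, w_j < lo
    if disc_i and disc_j:
        return -1 if dev <= 0 else +1
    if amb_i and amb_j:
        return -1
    if (disc_i and amb_j) or (amb_i and disc_j):
        return +1
    return -1 if dev <= 0 else +1


def key_pose_distance(
    kp_i: KeyPose,
    kp_j: KeyPose,
    avg: float,
    params: MatchParams = MatchParams(),
) -> float:
    """Relevance-adjusted distance between two key poses (may be negative)."""
    if kp_i.feature.shape != kp_j.feature.shape:
        raise ValueError("key-pose features have mismatched lengths")
    e = float(np.linalg.norm(kp_i.feature - kp_j.feature))
    if not params.use_relevance:
        return e
    dev = e - avg
    z = select_z(kp_i.weight, kp_j.weight, dev, params)
    mag = dev if params.signed_relevance else abs(dev)
    return e + z * mag * kp_i.weight * kp_j.weight


def bag_cost_matrix(bag: BagOfKeyPoses, params: MatchParams = MatchParams()) -> np.ndarray:
    """Pairwise relevance-adjusted cost between all key poses of a bag.

    Vectorised equivalent of :func:`key_pose_distance` on every pair;
    computed once per model so DTW cost matrices become index lookups.
    """
    F = bag.feature_matrix
    e = cdist(F, F)
    if not params.use_relevance:
        return e
    w = bag.weights
    dev = e - bag.average_distance
    lo, hi = params.ambiguous_threshold, params.discriminative_threshold
    disc = w > hi
    amb = w < lo
    both_disc = disc[:, None] & disc[None, :]
    both_amb = amb[:, None] & amb[None, :]
    mixed = (disc[:, None] & amb[None, :]) | (amb[:, None] & disc[None, :])
    sign_rule = np.where(dev <= 0, -1.0, 1.0)
    z = sign_rule.copy()
    z[both_amb] = -1.0
    z[mixed] = 1.0
    z[both_disc] = sign_rule[both_disc]
    mag = dev if params.signed_relevance else np.abs(dev)
    return e + z * mag * (w[:, None] * w[None, :])


def dtw_from_cost(cost: np.ndarray) -> float:
    """Classical DTW distance given a precomputed (t, u) pair-cost matrix.

    Recursion ``dtw(i,j) = min(dtw(i-1,j), dtw(i,j-1), dtw(i-1,j-1)) +
    cost(i,j)`` with dtw(0,0) = 0 and an infinite first row/column; no
    windowing, slope constraint or path-length normalisation.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be non-empty and 2-D")
    t, u = cost.shape
    prev = np.full(u + 1, np.inf)
    prev[0] = 0.0
    for i in range(t):
        row = np.empty(u + 1)
        row[0] = np.inf
        ci = cost[i]
        for j in range(1, u + 1):
            row[j] = min(prev[j], row[j - 1], prev[j - 1]) + ci[j - 1]
        prev = row
    return float(prev[u])


def dtw_distance(a: KeyPoseSequence, b: KeyPoseSequence, cost: np.ndarray) -> float:
    """DTW distance between two key-pose sequences over the same bag.

    ``cost`` is the bag-level pairwise cost matrix
    (:func:`bag_cost_matrix`); the sequence-level cost matrix is the
    lookup ``cost[a_i, b_j]``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty key-pose sequence")
    return dtw_from_cost(cost[np.ix_(a.indices, b.indices)])


def classify(
    test_views: dict[str, np.ndarray],
    model: ActionModel,
    params: MatchParams = MatchParams(),
) -> RecognitionResult:
    """Label a multiview test sequence by best-view DTW nearest neighbour.

    ``test_views`` maps view names to (T, S) frame-feature arrays (a
    single entry performs single-view recognition).  Each view stream is
    rewritten as key poses via the bag, matched by DTW against *all*
    stored training sequences (from every view: same-view matches are
    naturally closer because key poses are view-specific), and the
    training sequence with the globally lowest distance decides the label
    and the best view.  Ties go to the lowest training-sequence index and
    the first view in sorted order.
    """
    if not test_views:
        raise ValueError("no test views supplied")
    if not model.sequences:
        raise ValueError("model holds no training key-pose sequences")
    cost = bag_cost_matrix(model.bag, params)

    per_view: dict[str, tuple[float, str, str]] = {}
    best = None  # (distance, view, seq_label, seq_id)
    for view in sorted(test_views):
        frames = np.asarray(test_views[view], dtype=float)
        idx, _ = _nearest_indices(frames, model.bag)
        test_seq = KeyPoseSequence(
            indices=idx, action_class="?", view=view, actor="?", sequence_id="?"
        )
        view_best = None
        for train_seq in model.sequences:
            d = dtw_distance(test_seq, train_seq, cost)
            if view_best is None or d < view_best[0]:
                view_best = (d, train_seq.action_class, train_seq.sequence_id)
        per_view[view] = view_best
        if best is None or view_best[0] < best[0]:
            best = (view_best[0], view, view_best[1], view_best[2])

    return RecognitionResult(
        predicted_class=best[2],
        best_view=best[1],
        best_training_sequence_id=best[3],
        distance=best[0],
        per_view_distances=per_view,
    )
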