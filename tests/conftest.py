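"""Shared fixtures and independent reference implementations.

The reference implementations here deliberately avoid the package's
vectorised code paths: the radial feature oracle loops over contour
points one at a time with scalar math, and the DTW oracle enumerates
every monotone warping path.  They exist so the package can be checked
against literal, unoptimised evaluations of the same definitions.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from keyposes import EvalConfig, SynthConfig, generate_dataset, run_loso


# ---------------------------------------------------------------------------
# brute-force radial feature (scalar, per-point)
# ---------------------------------------------------------------------------

def brute_force_feature(points, S: int, summary: str) -> np.ndarray:
    """Literal per-point evaluation of the radial descriptor.

    Centroid -> per-point distance -> per-point angle/bin -> per-bin
    summary -> unit-sum normalisation, all with scalar ``math`` calls.
    """
    n = len(points)
    xc = sum(p[0] for p in points) / n
    yc = sum(p[1] for p in points) / n

    bins: dict[int, list[float]] = {j: [] for j in range(1, S + 1)}
    for (x, y) in points:
        d = math.sqrt((x - xc) ** 2 + (y - yc) ** 2)
        if d == 0.0:
            bins[1].append(0.0)
            continue
        ratio = max(-1.0, min(1.0, (y - yc) / d))
        base = math.degrees(math.acos(ratio))
        alpha = base if (x - xc) >= 0 else 360.0 - base
        if alpha == 0.0:
            alpha = 360.0
        s = math.ceil(S * alpha / 360.0)
        bins[s].append(d)

    v = []
    for j in range(1, S + 1):
        ds = bins[j]
        if not ds:
            v.append(0.0)
        elif summary == "variance":
            mu = sum(ds) / len(ds)
            v.append(sum((d - mu) ** 2 for d in ds))
        elif summary == "max":
            v.append(max(ds))
        elif summary == "range":
            v.append(max(ds) - min(ds))
    total = sum(v)
    if total < 1e-9:
        return np.zeros(S)
    return np.array([x / total for x in v])


def random_polygon(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """A random star-shaped polygon as an (n, 2) float point list."""
    if n is None:
        n = int(rng.integers(3, 200))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(2.0, 30.0, size=n)
    center = rng.uniform(-50, 50, size=2)
    return np.stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)],
        axis=1,
    )


# ---------------------------------------------------------------------------
# exhaustive DTW over all monotone warping paths
# ---------------------------------------------------------------------------

def enumerate_dtw(cost: np.ndarray) -> float:
    """Minimum path sum over every monotone warping path from (0,0) to
    (t-1, u-1) with steps down, right, or diagonal (pure recursion)."""
    t, u = cost.shape

    def best(i, j):
        here = cost[i, j]
        if i == 0 and j == 0:
            return here
        options = []
        if i > 0:
            options.append(best(i - 1, j))
        if j > 0:
            options.append(best(i, j - 1))
        if i > 0 and j > 0:
            options.append(best(i - 1, j - 1))
        return here + min(options)

    return float(best(t - 1, u - 1))


# ---------------------------------------------------------------------------
# shared datasets (expensive; extracted once per session)
# ---------------------------------------------------------------------------

CLEAN_SYNTH = SynthConfig(seed=0)  # 3 classes, 2 views, 3 actors, 2 seqs, 20 frames
STUDY_CONFIG = EvalConfig(S=12, K=3, summary="range", seed=0)


@pytest.fixture(scope="session")
def clean_dataset():
    return generate_dataset(CLEAN_SYNTH)


@pytest.fixture(scope="session")
def clean_loso_report(clean_dataset):
    return run_loso(clean_dataset, STUDY_CONFIG)
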