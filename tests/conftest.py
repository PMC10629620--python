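import numpy as np
import pytest

from gliaquant import random_scene, render_scene


@pytest.fixture(scope="session")
def noise_free_scene():
    spec = random_scene(seed=42, noise_sd=0.0)
    channels, truth = render_scene(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def noisy_scene():
    spec = random_scene(seed=7, noise_sd=5.0)
    channels, truth = render_scene(spec)
    return spec, channels, truth


def brute_force_otsu(data: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance scan over all candidate bin edges.

    Independent oracle: plain per-candidate loop with direct sums, no
    cumulative shortcuts. Ties go to the lowest edge.
    """
    data = np.asarray(data, dtype=float).ravel()
    lo, hi = data.min(), data.max()
    hist, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_k, best_v = None, -np.inf
    for k in range(1, n_bins):
        if hist[k - 1] == 0:
            continue  # same data partition as the gap's lower edge: an exact tie
        w0 = hist[:k].sum()
        w1 = hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_k = v, k
    return float(edges[best_k])


def brute_force_axis_ratio(voxel_coords: np.ndarray) -> float:
    """Axis ratio from raw voxel moments: explicit covariance, 1/12 per axis."""
    c = voxel_coords.astype(float)
    c = c - c.mean(axis=0)
    cov = np.zeros((3, 3))
    for row in c:
        cov += np.outer(row, row)
    cov /= len(c)
    cov += np.eye(3) / 12.0
    ev = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt(ev[2] / ev[0]))


def flood_fill_labels(binary: np.ndarray, connectivity: int) -> int:
    """Count connected components by BFS; oracle for binarize_and_label."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    todo = {tuple(c) for c in np.argwhere(binary)}
    n_components = 0
    while todo:
        n_components += 1
        stack = [todo.pop()]
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in todo:
                    todo.remove(nb)
                    stack.append(nb)
    return n_components
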