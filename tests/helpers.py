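"""Shared synthetic-data helpers for the test suite."""

import math

import numpy as np


def make_walk_tracks(rng, n_tracks, n_steps, d_per_min, beta=1.0):
    """Centroid tracks with MSD(dt) = 4 D dt^beta, dt in minutes.

    Fractional Gaussian increments are generated exactly by Cholesky
    factorization of the fGn covariance (Hurst index H = beta/2); beta = 1
    reduces to an ordinary random walk.
    """
    H = beta / 2.0
    k = np.arange(n_steps)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * H)
        - 2 * np.abs(k) ** (2 * H)
        + np.abs(k - 1.0) ** (2 * H)
    )
    cov = np.empty((n_steps, n_steps))
    for i in range(n_steps):
        for j in range(n_steps):
            cov[i, j] = gamma[abs(i - j)]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    sigma2 = 2 * d_per_min  # per-axis variance of a 1-min increment
    tracks = []
    for _ in range(n_tracks):
        incs = chol @ rng.standard_normal((n_steps, 2)) * math.sqrt(sigma2)
        pos = np.vstack([[0.0, 0.0], np.cumsum(incs, axis=0)])
        tracks.append(np.mod(pos, 1e6))  # effectively unwrapped
    return tracks
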