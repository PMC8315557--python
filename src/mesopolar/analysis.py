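"""Cluster and mobility statistics for simulated membrane point patterns.

Implements the quantification pipeline used on polarity simulations:

* ``H(r)`` — a Besag-L-type transform of the cumulative pairwise-distance
  distribution on the periodic square; 0 for spatially uniform patterns,
  positive maxima mark clustering at that length scale;
* the scalar polarization metric H(r = 1.1 μm) over active Cdc42;
* toroidal centroid tracking, MSD of the patch centroid, and the effective
  patch diffusivity ``D_patch`` with anomaly exponent β from the log-log fit
  ``log MSD(Δt) = log(4 D_patch) + β log Δt``;
* the spatial-fluctuation measure ``CV_patch`` (abundance-weighted average
  over locations of the temporal coefficient of variation);
* tagged-species washout dwell times with single-exponential fits.

All statistics use minimum-image distances and are invariant to global
translations (mod L) of the input pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import rdme
from .model import (
    Compartment,
    ModelSpec,
    add_tagged_species,
    is_tagged,
    tagged_name,
)
from .trajectory import Trajectory

__all__ = [
    "HrCurve",
    "MsdFit",
    "DwellFit",
    "ACTIVE_CDC42",
    "pairwise_distribution",
    "H_of_r",
    "h_at",
    "polarization_metric",
    "polarization_time",
    "centroid_torus",
    "centroid_track",
    "msd_and_dpatch",
    "cv_patch",
    "fit_exponential_dwell",
    "measure_dwell_time",
]

#: species whose positions constitute "active Cdc42" (tagged twins included
#: automatically where present)
ACTIVE_CDC42 = ("Cdc42T", "Cdc42T_GEF")


def _pairwise_distances(points: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image distances of all unordered pairs (chunked O(N²))."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("pairwise statistics require at least 2 points")
    chunks = []
    block = max(1, int(4e6 / max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = points[start:stop, None, :] - points[None, :, :]
        d -= np.round(d / L) * L
        dist = np.sqrt((d**2).sum(-1))
        for row in range(stop - start):
            chunks.append(dist[row, start + row + 1 :])
    return np.concatenate(chunks)


def pairwise_distribution(
    points: np.ndarray,
    L: float,
    bin_width: float = 0.05,
    r_max: float | None = None,
):
    """Pairwise-distance density P(r) on bins of width ``bin_width``.

    P(r) is the histogram of ordered pairwise distances normalized by the
    N(N-1) comparisons and by the bin width; for a uniform pattern
    P(r) → 2πr/A at r ≪ L/2, and ∫P dr ≤ 1 over [0, L/2].
    Returns (bin_edges, P).
    """
    if r_max is None:
        r_max = L / 2.0
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    dist = _pairwise_distances(points, L)
    n = len(points)
    counts, _ = np.histogram(dist, bins=edges)
    # unordered pairs counted once; Eq-level normalization is over ordered
    # comparisons, so each pair contributes twice
    P = 2.0 * counts / (n * (n - 1) * bin_width)
    return edges, P


@dataclass(frozen=True)
class HrCurve:
    """H(r) with its ingredients on a common binning.

    ``r`` are bin right-edges; ``K`` is the cumulative pair fraction
    (Ripley-K-style CDF), ``H = √(A·K/π) − r``.
    """

    r: np.ndarray
    P: np.ndarray
    K: np.ndarray
    H: np.ndarray
    L: float
    n_points: int

    def at(self, r: float) -> float:
        """H evaluated at radius r (nearest computed bin edge)."""
        idx = int(np.argmin(np.abs(self.r - r)))
        return float(self.H[idx])

    @property
    def argmax_r(self) -> float:
        return float(self.r[int(np.argmax(self.H))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, "P": self.P, "K": self.K, "H": self.H})


def H_of_r(
    points: np.ndarray,
    L: float,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> HrCurve:
    """Clustering function H(r) of a periodic point pattern.

    ``H(r) = √(A/π · ∫₀ʳ P) − r`` vanishes for an unstructured pattern,
    is negative for dispersion and positive for aggregation; the location of
    its maximum estimates the cluster length scale.  Distances are
    minimum-image, so ``r_max`` defaults to L/2.
    """
    edges, P = pairwise_distribution(points, L, bin_width, r_max)
    K = np.cumsum(P) * bin_width
    r = edges[1:]
    H = np.sqrt(L * L * K / math.pi) - r
    return HrCurve(r=r, P=P, K=K, H=H, L=L, n_points=len(points))


def h_at(points: np.ndarray, L: float, r: float = 1.1, bin_width: float = 0.05) -> float:
    return H_of_r(points, L, bin_width, r_max=max(r + bin_width, 2 * bin_width)).at(r)


def _active_species(traj: Trajectory) -> list[str]:
    names = []
    for base in ACTIVE_CDC42:
        for name in traj.species_names:
            if name == base or (is_tagged(name) and name == tagged_name(base)):
                names.append(name)
    return names


def polarization_metric(
    traj: Trajectory,
    r: float = 1.1,
    bin_width: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """H(r = 1.1 μm) of active Cdc42 (Cdc42T + Cdc42T-GEF) per snapshot.

    RDME snapshots are converted to pseudo-coordinates sampled within voxels.
    Snapshots with fewer than 2 active molecules yield NaN (flagged, not
    fatal).  Returns (times, metric).
    """
    rng = np.random.default_rng(seed)
    species = _active_species(traj)
    out = np.full(len(traj.times), np.nan)
    for i in range(len(traj.times)):
        pts = traj.points_at(i, species, rng=rng)
        if len(pts) >= 2:
            out[i] = H_of_r(pts, traj.L, bin_width).at(r)
    return traj.times.copy(), out


def polarization_time(
    times: np.ndarray,
    sd_series: np.ndarray,
    tolerance: float = 0.1,
    tail: float = 60.0,
) -> float:
    """Time at which the ensemble SD of the polarization metric stabilizes.

    Operationalized as the earliest time after which the SD stays within
    ±``tolerance`` (relative) of its mean over the final ``tail`` seconds.
    """
    times = np.asarray(times, dtype=float)
    sd = np.asarray(sd_series, dtype=float)
    ref = sd[times >= times[-1] - tail].mean()
    if ref <= 0:
        raise ValueError("reference SD is not positive")
    within = np.abs(sd - ref) <= tolerance * ref
    for i in range(len(times)):
        if within[i:].all():
            return float(times[i])
    return float(times[-1])


def centroid_torus(points: np.ndarray, L: float) -> np.ndarray:
    """Centroid of a periodic point pattern via per-axis circular means.

    Each coordinate is mapped to an angle 2πx/L, unit vectors are averaged
    and mapped back, so clusters straddling the boundary are handled
    correctly.  Raises if the pattern has no directional concentration
    (resultant length ≈ 0), in which case no centroid is defined.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty pattern has no centroid")
    out = np.empty(2)
    for ax in range(2):
        theta = 2.0 * math.pi * points[:, ax] / L
        c, s = np.cos(theta).mean(), np.sin(theta).mean()
        if math.hypot(c, s) < 1e-12:
            raise ValueError("centroid undefined: no directional concentration")
        out[ax] = (math.atan2(s, c) % (2.0 * math.pi)) * L / (2.0 * math.pi)
    return out


def centroid_track(
    traj: Trajectory,
    interval: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Active-Cdc42 centroid sampled every ``interval`` seconds.

    Returns (times, centroids (T, 2)); snapshots with an empty active set
    give NaN rows.
    """
    rng = np.random.default_rng(seed)
    species = _active_species(traj)
    sel = []
    next_t = traj.times[0]
    for i, t in enumerate(traj.times):
        if t >= next_t - 1e-9:
            sel.append(i)
            next_t = t + interval
    times = traj.times[sel]
    cents = np.full((len(sel), 2), np.nan)
    for k, i in enumerate(sel):
        pts = traj.points_at(i, species, rng=rng)
        if len(pts):
            cents[k] = centroid_torus(pts, traj.L)
    return times, cents


@dataclass(frozen=True)
class MsdFit:
    """MSD curve with the D_patch / β log-log fit.

    ``dt`` is in minutes and ``d_patch`` in μm²/min.  ``msd`` is the raw
    curve; when ``baseline`` is not None it was subtracted before fitting
    (the MSD at the smallest interval reflects within-patch jitter, not
    long-range transport).
    """

    dt: np.ndarray  # minutes
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray
    d_patch: float  # μm²/min
    beta: float
    d_patch_se: float
    beta_se: float
    baseline: float | None
    fit_window: tuple[float, float]


def _sub_tracks(track: np.ndarray, L: float, max_jump: float) -> list[np.ndarray]:
    """Unwrap a toroidal centroid track; break at jumps larger than max_jump
    (and at NaN gaps).  Returns unwrapped sub-tracks in the plane."""
    subs: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    prev = None
    pos = np.zeros(2)
    for row in track:
        if np.any(np.isnan(row)):
            prev = None
            if len(current) > 1:
                subs.append(current)
            current = []
            continue
        if prev is None:
            pos = np.zeros(2)
            current = [pos.copy()]
        else:
            step = row - prev
            step -= np.round(step / L) * L
            if np.hypot(*step) > max_jump:
                if len(current) > 1:
                    subs.append(current)
                current = [np.zeros(2)]
                pos = np.zeros(2)
            else:
                pos = pos + step
                current.append(pos.copy())
        prev = row
    if len(current) > 1:
        subs.append(current)
    return [np.array(s) for s in subs]


def msd_and_dpatch(
    tracks: Sequence[np.ndarray],
    L: float,
    sample_interval: float = 60.0,
    max_jump: float = 6.0,
    fit_window: tuple[float, float] = (2.0, 10.0),
    baseline_subtract: bool = True,
) -> MsdFit:
    """Pooled MSD of centroid tracks and the D_patch / β fit.

    ``tracks`` are toroidal centroid positions sampled every
    ``sample_interval`` seconds (NaN rows mark undefined centroids).  Tracks
    are unwrapped with minimum-image steps and broken into sub-trajectories
    at jumps exceeding ``max_jump`` (boundary-crossing artifacts).  MSD(Δt)
    pools all interval pairs over all sub-trajectories.  When
    ``baseline_subtract`` is on, MSD at the smallest interval is subtracted
    from the curve before the log-log least-squares fit of
    ``log MSD = log(4 D_patch) + β log Δt`` over ``fit_window`` (minutes).
    Note the subtraction is meant to remove within-patch jitter; applied to
    a noise-free random walk it biases β upward.
    """
    subs: list[np.ndarray] = []
    for tr in tracks:
        subs.extend(_sub_tracks(np.asarray(tr, dtype=float), L, max_jump))
    if not subs:
        raise ValueError("no usable sub-trajectories")
    max_lag = max(len(s) for s in subs) - 1
    if max_lag < 1:
        raise ValueError("tracks too short for MSD")
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for s in subs:
        n = len(s)
        for lag in range(1, n):
            d = s[lag:] - s[:-lag]
            sums[lag] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            counts[lag] += n - lag
    valid = counts[1:] > 0
    lags = np.arange(1, max_lag + 1)[valid]
    msd = sums[1:][valid] / counts[1:][valid]
    dt_min = lags * sample_interval / 60.0

    baseline = None
    y = msd.copy()
    if baseline_subtract:
        baseline = float(msd[0])
        y = msd - baseline
    lo, hi = fit_window
    mask = (dt_min >= lo - 1e-9) & (dt_min <= hi + 1e-9) & (y > 0)
    if mask.sum() < 3:
        raise ValueError(
            "fewer than 3 usable MSD points in the fit window "
            f"{fit_window} min after baseline subtraction"
        )
    res = stats.linregress(np.log(dt_min[mask]), np.log(y[mask]))
    d_patch = math.exp(res.intercept) / 4.0
    return MsdFit(
        dt=dt_min,
        msd=msd,
        n_pairs=counts[1:][valid],
        d_patch=d_patch,
        beta=float(res.slope),
        d_patch_se=d_patch * float(res.intercept_stderr),
        beta_se=float(res.stderr),
        baseline=baseline,
        fit_window=fit_window,
    )


def cv_patch(field: np.ndarray) -> float:
    """Abundance-weighted spatial average of the temporal CV of a count field.

    ``field`` has shape (T, ...): local counts (e.g. active Cdc42 per voxel)
    sampled at regular intervals (1 s in the reference pipeline) over a
    window short enough (1 min) that the mean pattern does not relocate.
    Per location j, CV_j = SD_j/mean_j over time; locations are averaged
    with weights ⟨count_j⟩.  For independent Poisson counts of mean μ this
    tends to 1/√μ; a temporally constant field gives 0.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim < 2 or field.shape[0] < 2:
        raise ValueError("need a (T, locations) field with T >= 2")
    flat = field.reshape(field.shape[0], -1)
    mean = flat.mean(axis=0)
    if not np.any(mean > 0):
        raise ValueError("all-zero field: CV_patch undefined")
    sd = flat.std(axis=0, ddof=0)
    cv = np.zeros_like(mean)
    pos = mean > 0
    cv[pos] = sd[pos] / mean[pos]
    return float(np.sum(cv * mean) / np.sum(mean))


@dataclass(frozen=True)
class DwellFit:
    """Single-exponential fit of a tagged-species washout decay."""

    dwell_time: float  # s
    rate: float  # s⁻¹
    rate_se: float
    fit_window: tuple[float, float]


def fit_exponential_dwell(
    times: np.ndarray,
    totals: np.ndarray,
    fit_start: float = 0.0,
    fit_end: float | None = None,
) -> DwellFit:
    """Fit ``totals ≈ A·exp(-t/τ)`` on [fit_start, fit_end]; returns τ.

    The fit is least squares on log-counts (zeros dropped), so the initial
    fast transient — e.g. membrane detachment of inactive Cdc42 — can be
    excluded by choosing ``fit_start`` after it.  A non-decaying series
    raises (tagging leak diagnostic).
    """
    times = np.asarray(times, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if fit_end is None:
        fit_end = times[-1]
    mask = (times >= fit_start) & (times <= fit_end) & (totals > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 positive points in the fit window")
    res = stats.linregress(times[mask], np.log(totals[mask]))
    if res.slope >= 0:
        raise ValueError(
            "tagged totals do not decay over the fit window (tagging leak?)"
        )
    rate = -float(res.slope)
    return DwellFit(
        dwell_time=1.0 / rate,
        rate=rate,
        rate_se=float(res.stderr),
        fit_window=(float(fit_start), float(fit_end)),
    )


def _voxel_centers(n: int, h: float) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(n) + 0.5) * h
    gx, gy = np.meshgrid(c, c)  # gx varies along axis 1 (x), gy along axis 0
    return gx, gy


def measure_dwell_time(
    model: ModelSpec,
    config: "rdme.GridConfig",
    unit: str = "cdc42",
    t_equilibrate: float = 100.0,
    t_record: float = 60.0,
    record_interval: float = 1.0,
    region_radius: float | None = None,
    fit_start: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[float, float, list[DwellFit]]:
    """Washout dwell time of ``unit`` ("cdc42" or "gef") at the patch.

    Per replicate: run the untagged model to steady state, convert the
    membrane species carrying ``unit`` into their tagged twins inside a
    region around the current patch centroid (default radius: the argmax of
    H(r), the measured cluster scale), continue the simulation and fit an
    exponential to the decay of the tagged totals (a tagged molecule that
    detaches to the cytosol reverts to the untagged form, so the decay
    measures residence at the patch).  Returns (mean, SD, fits).
    """
    import dataclasses as _dc

    tagged_model = add_tagged_species(model, unit)
    shadow = [
        s.name
        for s in model.species
        if s.compartment is Compartment.MEMBRANE and s.composition.get(unit, 0) > 0
    ]
    fits: list[DwellFit] = []
    for rep in range(n_replicates):
        cfg_eq = _dc.replace(
            config,
            t_end=t_equilibrate,
            record_interval=t_equilibrate,
            seed=seed + 7919 * rep,
            record_voxels=True,
        )
        traj = rdme.run(model, cfg_eq)
        grid = traj.counts[-1]  # (S, n, n)
        n = grid.shape[-1]
        rng = np.random.default_rng(seed + rep)
        # the patch is located from active Cdc42 when present, otherwise
        # from the membrane species being tagged
        centroid_species = _active_species(traj) or shadow
        pts = traj.points_at(len(traj.times) - 1, centroid_species, rng=rng)
        if len(pts) < 2:
            raise ValueError("no polarity patch present at tagging time")
        center = centroid_torus(pts, traj.L)
        radius = region_radius
        if radius is None:
            radius = H_of_r(pts, traj.L).argmax_r
        gx, gy = _voxel_centers(n, config.h)
        dx = gx - center[0]
        dx -= np.round(dx / config.L) * config.L
        dy = gy - center[1]
        dy -= np.round(dy / config.L) * config.L
        in_region = dx * dx + dy * dy <= radius * radius

        S_tagged = len(tagged_model.species)
        counts0 = np.zeros((S_tagged, n, n), dtype=np.int64)
        for s_i, sp in enumerate(model.species):
            counts0[tagged_model.species_index(sp.name)] = grid[s_i]
        for name in shadow:
            src = tagged_model.species_index(name)
            dst = tagged_model.species_index(tagged_name(name))
            moved = np.where(in_region, counts0[src], 0)
            counts0[dst] += moved
            counts0[src] -= moved

        cfg_rec = _dc.replace(
            config,
            t_end=t_record,
            record_interval=record_interval,
            seed=seed + 7919 * rep + 1,
            record_voxels=False,
        )
        traj2 = rdme.run(tagged_model, cfg_rec, initial_counts=counts0)
        tagged_idx = [
            tagged_model.species_index(tagged_name(name)) for name in shadow
        ]
        totals = traj2.totals[:, tagged_idx].sum(axis=1)
        fits.append(fit_exponential_dwell(traj2.times, totals, fit_start))
    dwells = np.array([f.dwell_time for f in fits])
    return float(dwells.mean()), float(dwells.std(ddof=0)), fits
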