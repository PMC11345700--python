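"""Synthetic fMRI phantoms with known regions of activation.

This module builds 4D BOLD phantoms on an ellipsoidal digital brain: four
ground-truth regions of activation (ROAs) of fixed voxel counts, a landmark-
calibrated hemodynamic response function (HRF), an event design convolved
with that HRF, and calibrated Gaussian or Rician noise.  Every quantity that
downstream evaluation treats as "truth" (mask voxels, per-voxel BOLD
magnitude, the task regressor) is carried on the :class:`Phantom4D` object.

Conventions
-----------
* Grids are isotropic; coordinates are 0-based voxel indices ``(x, y, z)``.
* BOLD magnitudes are percent of the local baseline intensity.
* Noise levels are percent; in ``target_tsnr`` mode a level of ``L`` percent
  yields an in-brain temporal SNR of ``40 / L`` (40 at 1 %, 20 at 2 %, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import argrelmin

from .exceptions import CalibrationError, DesignError, GridError, PlacementError

__all__ = [
    "GridSpec",
    "ROAMask",
    "HRFSpec",
    "NoiseSpec",
    "Phantom4D",
    "make_baseline",
    "make_roa_masks",
    "make_hrf",
    "make_design",
    "default_onsets",
    "make_phantom",
    "add_noise",
    "measure_tsnr",
    "HETERO_MAGNITUDES_PCT",
]

#: The three BOLD magnitudes mixed within each ROA in heterogeneous phantoms.
HETERO_MAGNITUDES_PCT = (6.0, 3.0, 1.5)

# Super-sampling step for HRF and design construction, seconds.
DEFAULT_DT_S = 0.1


@dataclass(frozen=True)
class GridSpec:
    """Acquisition geometry of a phantom time series."""

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.5
    tr_s: float = 1.2
    n_volumes: int = 600

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise GridError(f"all grid axes must be >= 16 voxels, got {self.shape}")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.n_volumes < 1:
            raise GridError("voxel size, TR and volume count must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class ROAMask:
    """A ground-truth region of activation.

    ``voxels`` is an ``(n, 3)`` integer array in the deterministic order the
    construction produced; ``magnitude_pct`` holds the per-voxel BOLD
    magnitude (percent of baseline) aligned with ``voxels``.
    """

    label: int
    voxels: np.ndarray
    magnitude_pct: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def to_dense(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.voxels.T)] = True
        return out

    def magnitude_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        if self.magnitude_pct is None:
            raise ValueError("mask carries no magnitudes")
        out = np.zeros(shape, dtype=float)
        out[tuple(self.voxels.T)] = self.magnitude_pct
        return out

    def centroid(self) -> np.ndarray:
        return self.voxels.mean(axis=0)

    def set_homogeneous(self, magnitude_pct: float) -> "ROAMask":
        return replace(self, magnitude_pct=np.full(self.n_voxels, float(magnitude_pct)))

    def set_heterogeneous(
        self, magnitudes_pct: tuple[float, float, float] = HETERO_MAGNITUDES_PCT
    ) -> "ROAMask":
        """Mix three magnitudes within the mask as concentric tertiles.

        Voxels are ranked by distance to the mask centroid and split into
        three equal-count shells: the innermost third carries the largest
        magnitude, the outermost the smallest.
        """
        d = np.linalg.norm(self.voxels - self.centroid(), axis=1)
        order = np.argsort(d, kind="stable")
        mags = np.empty(self.n_voxels)
        bounds = [0, self.n_voxels // 3, 2 * self.n_voxels // 3, self.n_voxels]
        for level, (a, b) in zip(sorted(magnitudes_pct, reverse=True),
                                 zip(bounds[:-1], bounds[1:])):
            mags[order[a:b]] = level
        return replace(self, magnitude_pct=mags)


@dataclass(frozen=True)
class HRFSpec:
    """Landmarks and component shapes of the synthetic HRF.

    The kernel is a three-gamma composite: a positive response gamma minus a
    scaled undershoot gamma minus a scaled initial-dip gamma, calibrated so
    the *composite* attains its landmarks at the requested times.
    """

    t_dip_s: float = 1.2
    t_peak_s: float = 4.8
    t_undershoot_s: float = 8.4
    t_end_s: float = 20.0
    dip_depth: float = 0.05
    undershoot_depth: float = 0.2
    shape_peak: float = 20.0
    shape_undershoot: float = 35.0
    shape_dip: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_dip_s < self.t_peak_s < self.t_undershoot_s < self.t_end_s):
            raise CalibrationError(
                "HRF landmarks must satisfy 0 < dip < peak < undershoot < end, got "
                f"{self.t_dip_s}, {self.t_peak_s}, {self.t_undershoot_s}, {self.t_end_s}"
            )
        if min(self.shape_peak, self.shape_undershoot, self.shape_dip) <= 1.0:
            raise CalibrationError("gamma shape parameters must exceed 1 (mode > 0)")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model attached to a phantom.

    ``level_pct`` follows the ladder 1/2/4/8/16; in ``target_tsnr`` mode the
    per-voxel noise SD is ``baseline * level_pct / 40`` so the in-brain tSNR
    is ``40 / level_pct``.  ``percent_of_baseline`` instead uses a global SD
    of ``level_pct / 100`` of the mean in-brain baseline.
    """

    kind: str = "gaussian"
    level_pct: float = 2.0
    scaling_mode: str = "target_tsnr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scaling_mode not in ("target_tsnr", "percent_of_baseline"):
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")
        if self.level_pct <= 0:
            raise ValueError("noise level must be positive")


@dataclass
class Phantom4D:
    """A 4D phantom plus everything needed to score detections against it."""

    data: np.ndarray
    grid: GridSpec
    baseline: np.ndarray
    brain_mask: np.ndarray
    masks: list[ROAMask]
    regressor: np.ndarray
    noise: NoiseSpec | None = None
    onsets_s: np.ndarray = field(default_factory=lambda: np.array([]))
    durations_s: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def truth_union(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for m in self.masks:
            out |= m.to_dense(self.grid.shape)
        return out

    @property
    def gt_magnitude_map(self) -> np.ndarray:
        """Ground-truth per-voxel BOLD magnitude (percent), zero outside ROAs."""
        out = np.zeros(self.grid.shape, dtype=float)
        for m in self.masks:
            out += m.magnitude_map(self.grid.shape)
        return out


# ---------------------------------------------------------------------------
# baseline and brain mask
# ---------------------------------------------------------------------------

#: Ellipsoid semi-axes as a fraction of the grid extent; 0.44 gives a brain
#: filling ~36 % of the field of view, comfortably inside the 30-70 % band.
_BRAIN_SEMIAXIS_FRACTION = 0.44
_BASELINE_INTENSITY = 1000.0


def _ellipsoid_radius(grid: GridSpec, margin_voxels: float = 0.0) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel (1.0 on the brain surface)."""
    shape = grid.shape
    center = [(s - 1) / 2.0 for s in shape]
    semi = [_BRAIN_SEMIAXIS_FRACTION * s - margin_voxels for s in shape]
    if min(semi) <= 0:
        raise GridError("margin exceeds brain semi-axis")
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi))
    return np.sqrt(r2)


def make_baseline(grid: GridSpec, mode: str = "uniform") -> tuple[np.ndarray, np.ndarray]:
    """Parametric anatomical baseline: an ellipsoidal digital brain.

    ``uniform`` gives a flat in-brain intensity; ``shell`` adds a radial
    gradient (brighter near the surface) emulating the receive-coil profile,
    so the in-brain tSNR varies spatially in ``percent_of_baseline`` noise.
    """
    if mode not in ("uniform", "shell"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    r = _ellipsoid_radius(grid)
    brain = r <= 1.0
    baseline = np.zeros(grid.shape, dtype=float)
    if mode == "uniform":
        baseline[brain] = _BASELINE_INTENSITY
    else:
        # surface (r=1) at full intensity, centre at 50 %
        baseline[brain] = _BASELINE_INTENSITY * (0.5 + 0.5 * r[brain])
    return baseline, brain


# ---------------------------------------------------------------------------
# ROA masks
# ---------------------------------------------------------------------------


def _digital_sphere(center: tuple[int, int, int], radius: float) -> np.ndarray:
    """All lattice points with squared distance <= radius**2, raster order."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2 + 1e-9
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    return offs + np.asarray(center, dtype=int)


def _grow_irregular(
    center: tuple[int, int, int], target_count: int, shape: tuple[int, int, int]
) -> np.ndarray:
    """Grow an irregular region from a radius-4 digital sphere.

    Repeatedly collects the 6-connected boundary of the current set and adds
    its voxels in raster-scan order until ``target_count`` is reached.  The
    partial final shell makes the shape asymmetric while keeping the
    construction fully deterministic.
    """
    seed = _digital_sphere(center, 4.0)
    if target_count < seed.shape[0]:
        raise PlacementError(
            f"irregular target count {target_count} below the {seed.shape[0]}-voxel seed"
        )
    dense = np.zeros(shape, dtype=bool)
    dense[tuple(seed.T)] = True
    members = [tuple(v) for v in seed]
    neighbors = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    while len(members) < target_count:
        boundary = set()
        for v in np.argwhere(dense):
            for d in neighbors:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and not dense[w]:
                    boundary.add(w)
        if not boundary:
            raise PlacementError("irregular growth exhausted the grid")
        for w in sorted(boundary):  # raster-scan order
            dense[w] = True
            members.append(w)
            if len(members) == target_count:
                break
    return np.array(members, dtype=int)


def default_roa_centers(grid: GridSpec) -> list[tuple[int, int, int]]:
    """Four well-separated centers on the mid-axial plane."""
    nx, ny, nz = grid.shape
    lo = lambda n: int(round(0.30 * (n - 1)))
    hi = lambda n: int(round(0.70 * (n - 1)))
    z = nz // 2
    return [
        (lo(nx), lo(ny), z),  # mask 1: small sphere
        (hi(nx), hi(ny), z),  # mask 2: irregular
        (lo(nx), hi(ny), z),  # mask 3: sphere
        (hi(nx), lo(ny), z),  # mask 4: sphere
    ]


def make_roa_masks(
    grid: GridSpec,
    centers: list[tuple[int, int, int]] | None = None,
    irregular_target_count: int = 903,
) -> list[ROAMask]:
    """Build the four ground-truth ROAs.

    Mask 1 is the inclusive digital sphere of radius 2 (33 voxels); masks 3
    and 4 are radius-4 spheres (257 voxels each); mask 2 is the deterministic
    irregular growth to ``irregular_target_count`` voxels.
    """
    if centers is None:
        centers = default_roa_centers(grid)
    if len(centers) != 4:
        raise PlacementError("exactly four ROA centers are required")
    r_margin = _ellipsoid_radius(grid, margin_voxels=6.0)
    for c in centers:
        if any(not (0 <= c[i] < grid.shape[i]) for i in range(3)):
            raise PlacementError(f"center {c} outside the grid")
        if r_margin[tuple(c)] > 1.0:
            raise PlacementError(f"center {c} closer than 6 voxels to the brain surface")

    vox = [
        _digital_sphere(centers[0], 2.0),
        _grow_irregular(centers[1], irregular_target_count, grid.shape),
        _digital_sphere(centers[2], 4.0),
        _digital_sphere(centers[3], 4.0),
    ]
    brain = _ellipsoid_radius(grid) <= 1.0
    dense_union = np.zeros(grid.shape, dtype=int)
    for v in vox:
        if np.any(~brain[tuple(v.T)]):
            raise PlacementError("an ROA mask leaves the brain")
        dense_union[tuple(v.T)] += 1
    if dense_union.max() > 1:
        raise PlacementError("ROA masks overlap")
    for i in range(4):
        for j in range(i + 1, 4):
            d2 = np.min(
                np.sum((vox[i][:, None, :] - vox[j][None, :, :]) ** 2, axis=2)
            )
            if d2 < 8.0**2:
                raise PlacementError(
                    f"masks {i + 1} and {j + 1} closer than 8 voxels (d={np.sqrt(d2):.1f})"
                )
    return [ROAMask(label=i + 1, voxels=v) for i, v in enumerate(vox)]


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------


def _gamma_peak_normalized(t: np.ndarray, shape: float, mode: float) -> np.ndarray:
    """Gamma density with the given mode, rescaled to a maximum of 1."""
    # density ~ t^(k-1) exp(-t/theta); mode = (k-1) theta
    k = shape
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(t > 0, t / mode, 0.0)
        g = np.where(t > 0, u ** (k - 1) * np.exp((k - 1) * (1.0 - u)), 0.0)
    return g


def _composite(t: np.ndarray, spec: HRFSpec, modes: tuple[float, float, float]) -> np.ndarray:
    m_peak, m_under, m_dip = modes
    return (
        _gamma_peak_normalized(t, spec.shape_peak, m_peak)
        - spec.undershoot_depth * _gamma_peak_normalized(t, spec.shape_undershoot, m_under)
        - spec.dip_depth * _gamma_peak_normalized(t, spec.shape_dip, m_dip)
    )


def make_hrf(spec: HRFSpec = HRFSpec(), dt_s: float = 0.01) -> np.ndarray:
    """Sample the landmark-calibrated HRF kernel on ``[0, t_end]`` at ``dt_s``.

    A deterministic coordinate search shifts the mode of each gamma component
    until the composite attains its dip, peak and undershoot at the requested
    times (within the calibration grid).  The composite is then rescaled to a
    maximum of 1 and smoothly tapered to exactly zero at ``t_end``.
    """
    if dt_s > 0.1:
        raise CalibrationError("dt_s must be <= 0.1 s for landmark calibration")
    dt_cal = min(dt_s, 0.01)
    t = np.arange(0.0, spec.t_end_s + dt_cal / 2, dt_cal)
    modes = [spec.t_peak_s, spec.t_undershoot_s, spec.t_dip_s]
    dip_window = (t > 0.25 * spec.t_dip_s) & (t < 0.5 * (spec.t_dip_s + spec.t_peak_s))
    # search window for the undershoot: past the peak, before the taper region
    under_window = (t > spec.t_peak_s) & (t < 0.5 * (spec.t_undershoot_s + spec.t_end_s))
    for _ in range(300):
        h = _composite(t, spec, tuple(modes))
        t_hat_peak = t[int(np.argmax(h))]
        t_hat_under = t[under_window][int(np.argmin(h[under_window]))]
        t_hat_dip = t[dip_window][int(np.argmin(h[dip_window]))]
        err = (spec.t_peak_s - t_hat_peak,
               spec.t_undershoot_s - t_hat_under,
               spec.t_dip_s - t_hat_dip)
        if max(abs(e) for e in err) <= 0.75 * dt_cal:
            break
        # damped, step-capped coordinate updates keep the search stable even
        # though the composite couples all three components
        modes = [m + float(np.clip(0.5 * e, -0.3, 0.3)) for m, e in zip(modes, err)]
        if min(modes) <= 0:
            raise CalibrationError("HRF calibration drove a component mode below zero")

    h = _composite(t, spec, tuple(modes))
    # cosine taper over the last 15 % of the support, exact zero at t_end
    t_taper = 0.85 * spec.t_end_s
    w = np.ones_like(t)
    tail = t >= t_taper
    w[tail] = 0.5 * (1.0 + np.cos(np.pi * (t[tail] - t_taper) / (spec.t_end_s - t_taper)))
    h = h * w
    h /= np.max(h)

    # validate the calibrated kernel before resampling
    i_peak = int(np.argmax(h))
    i_under = int(np.argmin(h))
    dip_vals = h[dip_window]
    local_minima = argrelmin(dip_vals)[0]
    ok = (
        abs(t[i_peak] - spec.t_peak_s) <= dt_s + 1e-9
        and abs(t[i_under] - spec.t_undershoot_s) <= dt_s + 1e-9
        and h[i_under] < 0
        and (local_minima.size > 0 or dip_vals[0] > dip_vals.min())
    )
    if not ok:
        raise CalibrationError(
            "HRF landmarks not achieved: "
            f"peak at {t[i_peak]:.3f}s, undershoot at {t[i_under]:.3f}s "
            f"(value {h[i_under]:.4f})"
        )
    if abs(dt_s - dt_cal) < 1e-12:
        return h
    # resample onto the requested grid
    t_out = np.arange(0.0, spec.t_end_s + dt_s / 2, dt_s)
    return np.interp(t_out, t, h)


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------


def default_onsets(grid: GridSpec, n_events: int = 8, isi_s: float = 90.0,
                   first_onset_s: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """The standard phantom design: 8 impulse events, 90 s apart, first at 30 s."""
    onsets = first_onset_s + isi_s * np.arange(n_events)
    return onsets, np.zeros(n_events)


def make_design(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    grid: GridSpec,
    hrf: np.ndarray,
    dt_s: float = DEFAULT_DT_S,
) -> np.ndarray:
    """Convolve an event/boxcar train with the HRF, sampled on the TR grid.

    Zero durations denote impulse events (a single ``dt`` sample).  The
    regressor is renormalized to a maximum of 1.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    durations_s = np.atleast_1d(np.asarray(durations_s, dtype=float))
    if onsets_s.shape != durations_s.shape:
        raise DesignError("onsets and durations must have equal length")
    if np.any(durations_s < 0):
        raise DesignError("durations must be nonnegative")
    if np.any(onsets_s < 0) or np.any(onsets_s >= grid.duration_s):
        raise DesignError("onsets must lie within the scan")
    n_fine = int(np.ceil(grid.duration_s / dt_s)) + 1
    train = np.zeros(n_fine)
    for on, dur in zip(onsets_s, durations_s):
        i0 = int(round(on / dt_s))
        i1 = max(i0 + 1, int(round((on + dur) / dt_s)))
        train[i0:min(i1, n_fine)] = 1.0
    conv = np.convolve(train, hrf)[:n_fine]
    idx = np.round(grid.frame_times_s / dt_s).astype(int)
    reg = conv[idx]
    peak = np.max(np.abs(reg))
    if peak > 0:
        reg = reg / peak
    return reg


# ---------------------------------------------------------------------------
# phantom assembly and noise
# ---------------------------------------------------------------------------


def make_phantom(
    grid: GridSpec = GridSpec(),
    bold_pct: float = 6.0,
    hetero: bool = False,
    baseline_mode: str = "uniform",
    centers: list[tuple[int, int, int]] | None = None,
    noise: NoiseSpec | None = None,
    hrf_spec: HRFSpec = HRFSpec(),
    onsets_s: np.ndarray | None = None,
    durations_s: np.ndarray | None = None,
) -> Phantom4D:
    """Assemble a complete phantom; optionally add noise in the same call.

    The noiseless signal at a mask voxel ``v`` with magnitude ``m`` percent is
    ``baseline(v) * (1 + m/100 * regressor(t))``; elsewhere it is the flat
    baseline.
    """
    if grid.n_volumes * grid.tr_s < (30.0 + 7 * 90.0) + 60.0 and onsets_s is None:
        raise GridError("scan too short for the default 8-event design")
    baseline, brain = make_baseline(grid, baseline_mode)
    masks = make_roa_masks(grid, centers)
    if hetero:
        masks = [m.set_heterogeneous() for m in masks]
    else:
        masks = [m.set_homogeneous(bold_pct) for m in masks]
    hrf = make_hrf(hrf_spec, dt_s=DEFAULT_DT_S)
    if onsets_s is None:
        onsets_s, durations_s = default_onsets(grid)
    elif durations_s is None:
        durations_s = np.zeros_like(np.atleast_1d(onsets_s), dtype=float)
    reg = make_design(onsets_s, durations_s, grid, hrf, dt_s=DEFAULT_DT_S)
    if grid.duration_s < np.max(onsets_s) + 60.0:
        raise GridError("scan must extend 60 s beyond the last onset")

    data = np.broadcast_to(
        baseline.astype(np.float32)[..., None], grid.shape + (grid.n_volumes,)
    ).copy()
    gt = np.zeros(grid.shape, dtype=np.float32)
    for m in masks:
        gt[tuple(m.voxels.T)] = m.magnitude_pct
    active = gt > 0
    data[active, :] = baseline[active, None].astype(np.float32) * (
        1.0 + gt[active, None] / 100.0 * reg[None, :].astype(np.float32)
    )
    ph = Phantom4D(
        data=data, grid=grid, baseline=baseline, brain_mask=brain, masks=masks,
        regressor=reg, onsets_s=np.atleast_1d(onsets_s),
        durations_s=np.atleast_1d(durations_s),
    )
    if noise is not None:
        ph = add_noise(ph, noise)
    return ph


def _noise_sigma_map(phantom: Phantom4D, noise: NoiseSpec) -> np.ndarray:
    if noise.scaling_mode == "target_tsnr":
        # sigma(v) = baseline(v) / (40 / level)  ->  in-brain tSNR = 40/level
        return phantom.baseline * (noise.level_pct / 40.0)
    ref = float(phantom.baseline[phantom.brain_mask].mean())
    return np.full(phantom.grid.shape, ref * noise.level_pct / 100.0)


def add_noise(phantom: Phantom4D, noise: NoiseSpec) -> Phantom4D:
    """Return a copy of the phantom with noise added to every voxel series.

    Gaussian noise is i.i.d. normal with the per-voxel SD implied by the
    scaling mode.  Rician noise follows the magnitude construction
    ``sigma * sqrt(n1^2 + n2^2)`` with independent standard-normal ``n1, n2``,
    added to the signal without mean-centering, so it carries a positive
    offset of ``sigma * sqrt(pi/2)``.
    """
    sigma = _noise_sigma_map(phantom, noise).astype(np.float32)
    rng = np.random.default_rng(noise.seed)
    shape = phantom.data.shape
    if noise.kind == "gaussian":
        eps = rng.standard_normal(shape, dtype=np.float32)
        data = phantom.data + sigma[..., None] * eps
    else:
        n1 = rng.standard_normal(shape, dtype=np.float32)
        n2 = rng.standard_normal(shape, dtype=np.float32)
        data = phantom.data + sigma[..., None] * np.sqrt(n1 * n1 + n2 * n2)
    return replace(phantom, data=data, noise=noise)


def measure_tsnr(series: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-voxel temporal SNR (mean / SD) and its finite-value mean over a mask.

    Voxels with zero temporal variance are flagged ``inf`` and excluded from
    the mean.
    """
    if series.shape[-1] < 10:
        raise GridError("tSNR needs at least 10 timepoints")
    mu = series.mean(axis=-1, dtype=np.float64)
    sd = series.std(axis=-1, ddof=1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mu / sd, np.inf)
    vals = tsnr[mask]
    finite = np.isfinite(vals)
    mean = float(vals[finite].mean()) if finite.any() else float("inf")
    return tsnr, mean
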