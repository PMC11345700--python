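"""Null-hypothesis battery: task analyses of task-free data.

Block (B1: 10 s on/off, B2: 30 s on/off) and event-related (E1: 2 s on /
6 s off, E2: pseudorandom 1-4 s on / 3-6 s off) paradigms are fitted to
time series that contain no task signal; every detection is a false
positive.  Shifted/randomized paradigm variants multiply the number of
analyses: 4 (B1) + 13 (B2) + 2 (E1) + 16 (E2) = 35 variants, hence
16 series x 35 = 560 analyses per filter chain.

Since acquired resting-state data cannot be redistributed, a synthetic
null generator stands in: temporally AR(1), spatially smoothed fields with
low-frequency drifts on the ellipsoidal digital brain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("awsom")
from scipy.ndimage import gaussian_filter

from . import grf
from .aws import AdaptiveWeightsModel, AWSParams, estimate_correlation
from .exceptions import DesignError
from .glm import GLMModel, build_design_matrix
from .phantom import GridSpec, HRFSpec, make_baseline, make_design, make_hrf
from .smoothing import SmoothSpec, gaussian_smooth

__all__ = [
    "Paradigm",
    "NullSeriesSpec",
    "NullResult",
    "gen_paradigms",
    "gen_null_series",
    "run_null_battery",
    "FILTER_CHAINS",
]

FILTER_CHAINS = ("unfiltered", "gauss_1x", "gauss_15x", "gauss_25x", "aws", "awsom")

_GAUSS_PRESET = {"gauss_1x": "g1x", "gauss_15x": "g15x", "gauss_25x": "g25x"}


@dataclass(frozen=True)
class Paradigm:
    """One onset/duration schedule of a paradigm family."""

    family: str
    variant_id: int
    onsets_s: np.ndarray
    durations_s: np.ndarray


@dataclass(frozen=True)
class NullSeriesSpec:
    """Synthetic task-free series: AR(1) in time, smooth in space, drifting.

    Defaults mirror a 10-min resting acquisition: 300 volumes at TR 2 s on a
    48-cube grid, lag-1 temporal autocorrelation 0.3, spatial smoothness
    2 voxels FWHM, and two low-frequency cosine drifts (periods 240 s and
    120 s, amplitudes in units of the noise SD) with smooth random spatial
    amplitude profiles.
    """

    grid: GridSpec = GridSpec(shape=(48, 48, 48), tr_s=2.0, n_volumes=300)
    ar1_rho: float = 0.3
    spatial_fwhm_voxels: float = 2.0
    drift_amplitudes: tuple[float, ...] = (1.0, 0.6)
    drift_periods_s: tuple[float, ...] = (240.0, 120.0)
    slow_noise_amplitude: float = 0.0
    slow_noise_rho: float = 0.98
    tsnr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0 or not 0.0 <= self.slow_noise_rho < 1.0:
            raise DesignError("AR(1) coefficients must lie in [0, 1)")
        if len(self.drift_amplitudes) != len(self.drift_periods_s):
            raise DesignError("drift amplitudes and periods must pair up")


@dataclass
class NullResult:
    """Aggregate false-positive statistics for one family x chain cell."""

    family: str
    chain: str
    n_analyses: int
    fwer: float
    fpr: float
    mean_clusters: float
    mean_voxels: float
    conjunction_map: np.ndarray

    def to_row(self) -> dict:
        return dict(family=self.family, chain=self.chain, n_analyses=self.n_analyses,
                    fwer=self.fwer, fpr=self.fpr, mean_clusters=self.mean_clusters,
                    mean_voxels=self.mean_voxels)


# ---------------------------------------------------------------------------
# paradigms
# ---------------------------------------------------------------------------


def _block(onset0: float, on_s: float, off_s: float, duration_s: float):
    onsets, durations = [], []
    t = onset0
    while t < duration_s:
        onsets.append(t)
        durations.append(min(on_s, duration_s - t))
        t += on_s + off_s
    return np.array(onsets), np.array(durations)


def gen_paradigms(scan_duration_s: float, e2_master_seed: int = 0) -> dict[str, list[Paradigm]]:
    """All paradigm variants per family.

    B1 (10 s on/off) shifted by {0, 5, 10, 15} s: 4 variants; B2 (30 s
    on/off) shifted by {0, 5, ..., 60} s: 13; E1 (2 s on / 6 s off) shifted
    by {0, 4} s: 2; E2: 16 seeded pseudorandom schedules with on ~ U[1, 4] s
    and off ~ U[3, 6] s snapped to 0.1 s.  Events are truncated at scan end.
    """
    if scan_duration_s < 600.0:
        raise DesignError("null battery needs at least 600 s of scan")
    out: dict[str, list[Paradigm]] = {"B1": [], "B2": [], "E1": [], "E2": []}
    for i, shift in enumerate(np.arange(0.0, 20.0, 5.0)):
        on, du = _block(shift, 10.0, 10.0, scan_duration_s)
        out["B1"].append(Paradigm("B1", i, on, du))
    for i, shift in enumerate(np.arange(0.0, 65.0, 5.0)):
        on, du = _block(shift, 30.0, 30.0, scan_duration_s)
        out["B2"].append(Paradigm("B2", i, on, du))
    for i, shift in enumerate((0.0, 4.0)):
        on, du = _block(shift, 2.0, 6.0, scan_duration_s)
        out["E1"].append(Paradigm("E1", i, on, du))
    for i in range(16):
        rng = np.random.default_rng(np.random.SeedSequence([e2_master_seed, 7919, i]))
        onsets, durations = [], []
        t = float(np.round(rng.uniform(0.0, 3.0), 1))
        while t < scan_duration_s:
            dur = float(np.round(rng.uniform(1.0, 4.0), 1))
            onsets.append(t)
            durations.append(min(dur, scan_duration_s - t))
            t += dur + float(np.round(rng.uniform(3.0, 6.0), 1))
        out["E2"].append(Paradigm("E2", i, np.array(onsets), np.array(durations)))
    return out


# ---------------------------------------------------------------------------
# synthetic null series
# ---------------------------------------------------------------------------


def gen_null_series(spec: NullSeriesSpec) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic task-free 4D series and its brain mask."""
    grid = spec.grid
    baseline, brain = make_baseline(grid, "uniform")
    rng = np.random.default_rng(spec.seed)
    sigma_vox = spec.spatial_fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def _smooth_unit_field() -> np.ndarray:
        w = rng.standard_normal(grid.shape)
        if sigma_vox > 0:
            w = gaussian_filter(w, sigma_vox)
            sd = w[brain].std()
            if sd > 0:
                w = w / sd
        return w.astype(np.float32)

    rho = spec.ar1_rho
    noise = np.empty(grid.shape + (grid.n_volumes,), dtype=np.float32)
    e = _smooth_unit_field()
    noise[..., 0] = e
    innov_scale = np.float32(np.sqrt(1.0 - rho**2))
    for t in range(1, grid.n_volumes):
        e = np.float32(rho) * e + innov_scale * _smooth_unit_field()
        noise[..., t] = e
    if spec.slow_noise_amplitude > 0:
        # an additional near-unit-root component emulating unmodelled
        # low-frequency physiological noise; a single AR(1) prewhitening
        # pass cannot remove the resulting two-component spectrum
        srho = np.float32(spec.slow_noise_rho)
        s_scale = np.float32(np.sqrt(1.0 - spec.slow_noise_rho**2))
        amp = np.float32(spec.slow_noise_amplitude)
        s = _smooth_unit_field()
        noise[..., 0] += amp * s
        for t in range(1, grid.n_volumes):
            s = srho * s + s_scale * _smooth_unit_field()
            noise[..., t] += amp * s

    tt = grid.frame_times_s
    drift = np.zeros(grid.shape + (grid.n_volumes,), dtype=np.float32)
    for amp, period in zip(spec.drift_amplitudes, spec.drift_periods_s):
        profile = amp * gaussian_filter(rng.standard_normal(grid.shape), 4.0)
        profile /= max(np.abs(profile[brain]).max(), 1e-12) / amp
        phase = rng.uniform(0.0, 2.0 * np.pi)
        course = np.cos(2.0 * np.pi * tt / period + phase).astype(np.float32)
        drift += profile.astype(np.float32)[..., None] * course[None, None, None, :]

    data = baseline.astype(np.float32)[..., None] * (
        1.0 + (noise + drift) / np.float32(spec.tsnr)
    )
    data[~brain] = 0.0
    return data, brain


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------


def _analyze_one(
    series: np.ndarray,
    brain: np.ndarray,
    grid: GridSpec,
    paradigm: Paradigm,
    chain: str,
    hrf: np.ndarray,
    inference: grf.InferenceParams,
    prewhiten: str = "ar1",
) -> grf.SignificanceMask:
    reg = make_design(paradigm.onsets_s, paradigm.durations_s, grid, hrf)
    res = GLMModel(series, build_design_matrix(reg), brain).fit(prewhiten=prewhiten)
    smooth = grf.estimate_smoothness(res.residuals, brain)
    if chain in ("aws", "awsom"):
        params = AWSParams.awsom() if chain == "awsom" else AWSParams.aws()
        adj = estimate_correlation(res.residuals, brain)
        state = AdaptiveWeightsModel(
            res.cope, res.varcope, brain, adj, params, dof=res.dof
        ).fit()
        return state.significance(smooth, inference)
    sig, _ = grf.cluster_correct(res.zmap, smooth, inference, brain)
    return sig


def run_null_battery(
    series_specs: list[NullSeriesSpec],
    families: tuple[str, ...] = ("B1", "B2", "E1", "E2"),
    chains: tuple[str, ...] = ("unfiltered", "awsom"),
    inference: grf.InferenceParams = grf.InferenceParams(),
    prewhiten: str = "ar1",
    e2_master_seed: int = 0,
    progress: callable = None,
) -> list[NullResult]:
    """Run every series x paradigm-variant analysis for the given chains.

    Gaussian chains smooth the series once per chain and reuse it across
    paradigms; AWS chains operate on the unfiltered GLM output.  Returns one
    :class:`NullResult` per family x chain with FWER (percent of analyses
    showing any active voxel), FPR (mean percent of brain voxels active),
    mean cluster/voxel counts and the voxelwise conjunction map.
    """
    if len(series_specs) < 2:
        raise DesignError("need at least 2 null series")
    grid = series_specs[0].grid
    paradigms = gen_paradigms(grid.duration_s, e2_master_seed=e2_master_seed)
    hrf = make_hrf(HRFSpec(), dt_s=0.1)
    conn = grf.connectivity_structure(inference.connectivity)

    acc: dict[tuple[str, str], dict] = {
        (f, c): dict(n=0, hits=0, vox=[], clus=[],
                     conj=np.zeros(grid.shape, dtype=np.int32))
        for f in families for c in chains
    }
    for spec in series_specs:
        if spec.grid != grid:
            raise DesignError("all null series must share one grid")
        raw, brain = gen_null_series(spec)
        for chain in chains:
            if chain in _GAUSS_PRESET:
                series = gaussian_smooth(
                    raw, SmoothSpec.from_preset(_GAUSS_PRESET[chain]), brain,
                    grid.voxel_size_mm,
                )
            else:
                series = raw
            for fam in families:
                for par in paradigms[fam]:
                    try:
                        sig = _analyze_one(series, brain, grid, par, chain, hrf,
                                           inference, prewhiten)
                    except Exception:  # noqa: BLE001 - skip degenerate analyses
                        log.exception(
                            "analysis failed (family=%s chain=%s seed=%s variant=%s)",
                            fam, chain, spec.seed, par.variant_id)
                        continue
                    cell = acc[(fam, chain)]
                    n_vox = sig.n_voxels
                    from scipy import ndimage as _ndi
                    _, n_clus = _ndi.label(sig.mask, structure=conn)
                    cell["n"] += 1
                    cell["hits"] += int(n_vox > 0)
                    cell["vox"].append(n_vox)
                    cell["clus"].append(n_clus)
                    cell["conj"] += sig.mask.astype(np.int32)
                    if progress is not None:
                        progress(fam, chain, spec.seed, par.variant_id, n_vox)

    n_brain = int(make_baseline(grid, "uniform")[1].sum())
    results = []
    for (fam, chain), cell in acc.items():
        n = cell["n"]
        results.append(NullResult(
            family=fam, chain=chain, n_analyses=n,
            fwer=100.0 * cell["hits"] / n,
            fpr=float(np.mean([100.0 * v / n_brain for v in cell["vox"]])),
            mean_clusters=float(np.mean(cell["clus"])),
            mean_voxels=float(np.mean(cell["vox"])),
            conjunction_map=cell["conj"],
        ))
    return results
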