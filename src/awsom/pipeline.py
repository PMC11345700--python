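"""End-to-end benchmark orchestration: phantom -> GLM -> filter -> inference
-> metrics, looped over noise levels, BOLD magnitudes and seeds."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grf, metrics
from .aws import AdaptiveWeightsModel, AWSParams, estimate_correlation
from .exceptions import ConfigError
from .glm import GLMModel, build_design_matrix
from .phantom import GridSpec, NoiseSpec, make_phantom
from .smoothing import SmoothSpec, gaussian_smooth

log = logging.getLogger("awsom")

__all__ = ["RunConfig", "cell_seed", "run_cell", "run_benchmark"]

_CHAIN_PRESETS = {"gauss_1x": "g1x", "gauss_15x": "g15x", "gauss_25x": "g25x"}


@dataclass
class RunConfig:
    """One benchmark run: the condition grid and the analysis settings."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_volumes: int = 600
    tr_s: float = 1.2
    voxel_size_mm: float = 1.5
    noise_kinds: tuple[str, ...] = ("gaussian",)
    noise_levels_pct: tuple[float, ...] = (1.0, 2.0, 4.0)
    bold_magnitudes_pct: tuple[float, ...] = (6.0,)
    hetero: bool = False
    chains: tuple[str, ...] = ("unfiltered", "awsom")
    n_seeds: int = 10
    master_seed: int = 0
    z_threshold: float = 3.1
    cluster_alpha: float = 0.05
    out_dir: str = "awsom_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "noise_kinds", "noise_levels_pct",
                    "bold_magnitudes_pct", "chains"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(shape=tuple(self.grid_shape), voxel_size_mm=self.voxel_size_mm,
                        tr_s=self.tr_s, n_volumes=self.n_volumes)

    @property
    def inference(self) -> grf.InferenceParams:
        return grf.InferenceParams(z_threshold=self.z_threshold,
                                   cluster_alpha=self.cluster_alpha)


def cell_seed(master_seed: int, *counters: int) -> int:
    """Independent per-cell seed from the master seed and cell counters."""
    ss = np.random.SeedSequence([int(master_seed)] + [int(c) for c in counters])
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    config: RunConfig,
    noise_kind: str,
    level_pct: float,
    bold_pct: float,
    chain: str,
    seed: int,
) -> pd.DataFrame:
    """One phantom -> analysis -> metrics evaluation; tidy per-scope rows."""
    grid = config.grid
    phantom = make_phantom(
        grid=grid, bold_pct=bold_pct, hetero=config.hetero,
        noise=NoiseSpec(kind=noise_kind, level_pct=level_pct, seed=seed),
    )
    series = phantom.data
    if chain in _CHAIN_PRESETS:
        series = gaussian_smooth(
            series, SmoothSpec.from_preset(_CHAIN_PRESETS[chain]),
            phantom.brain_mask, grid.voxel_size_mm,
        )
    res = GLMModel(series, build_design_matrix(phantom.regressor),
                   phantom.brain_mask).fit()
    smooth = grf.estimate_smoothness(res.residuals, phantom.brain_mask)
    if chain in ("aws", "awsom"):
        params = AWSParams.awsom() if chain == "awsom" else AWSParams.aws()
        adj = estimate_correlation(res.residuals, phantom.brain_mask)
        state = AdaptiveWeightsModel(res.cope, res.varcope, phantom.brain_mask,
                                     adj, params, dof=res.dof).fit()
        sig = state.significance(smooth, config.inference)
        cope_for_si = state.theta
    else:
        sig, _ = grf.cluster_correct(res.zmap, smooth, config.inference,
                                     phantom.brain_mask)
        cope_for_si = res.cope
    reports = metrics.per_mask_report(sig.mask, phantom.masks,
                                      phantom.brain_mask, cope=cope_for_si)
    frame = metrics.reports_to_frame(reports)
    frame.insert(0, "seed", seed)
    frame.insert(0, "chain", chain)
    frame.insert(0, "bold_pct", bold_pct)
    frame.insert(0, "noise_level_pct", level_pct)
    frame.insert(0, "noise_kind", noise_kind)
    return frame


def run_benchmark(config: RunConfig) -> pd.DataFrame:
    """Loop the full condition grid; per-cell failures are logged and skipped.

    Writes ``metrics_long.csv`` (every seed) and ``metrics_summary.csv``
    (mean and SD over seeds per condition x scope) under ``config.out_dir``
    and returns the summary frame.
    """
    rows = []
    for ik, kind in enumerate(config.noise_kinds):
        for il, level in enumerate(config.noise_levels_pct):
            for ib, bold in enumerate(config.bold_magnitudes_pct):
                for chain in config.chains:
                    for i_seed in range(config.n_seeds):
                        seed = cell_seed(config.master_seed, ik, il, ib, i_seed)
                        try:
                            rows.append(run_cell(config, kind, level, bold,
                                                 chain, seed))
                        except Exception:  # noqa: BLE001 - keep the grid going
                            log.exception(
                                "cell failed: %s level=%s bold=%s chain=%s seed=%s",
                                kind, level, bold, chain, seed)
    long = pd.concat(rows, ignore_index=True)
    keys = ["noise_kind", "noise_level_pct", "bold_pct", "chain", "scope"]
    summary = (
        long.groupby(keys)[["sa", "bs", "si"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
    ]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long.to_csv(out / "metrics_long.csv", index=False)
    summary.to_csv(out / "metrics_summary.csv", index=False)
    for metric in ("sa", "bs", "si"):
        heatmap_table(summary, metric).to_csv(out / f"heatmap_{metric}.csv")
    config.to_file(out / "config.yaml")
    return summary


def heatmap_table(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Noise-level x chain table of per-scope means (heat-map layout)."""
    return summary.pivot_table(
        index=["scope", "noise_level_pct"], columns="chain",
        values=f"{metric}_mean",
    ).round(2)
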