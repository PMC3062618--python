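"""Synthetic spot-level data with the noise structure the analysis assumes.

Signals are generated on the raw scanner scale as 2**(log2 model), where the
log2 model mirrors the analysis models:

    log2 signal(g, channel) = baseline_g + tau[g, stage]
                              + dye_effect * [dye == Cy5]
                              + a_array
                              + b(x, y) * dye_sign
                              + c(A0) * dye_sign / 2
                              + e

with a_array ~ N(0, array_sd^2) shared by both channels of an array,
e ~ N(0, noise_sd^2) independent per gene per channel, b a spatial bias
field, c an intensity-dependent bias (dye_sign = +1 for Cy5, -1 for Cy3, so
the log-ratio M picks up 2*b + c), and A0 the bias-free log2 intensity.
Herring-sperm control spots carry non-specific signal drawn from
N(control_mean, control_sd^2) truncated at zero, independent per channel.

Every random draw is recorded in a truth record so downstream fits can be
checked against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .design import LoopDesign
from .exceptions import LayoutError

SPOT_COLUMNS = [
    "array_id",
    "subgrid",
    "row",
    "col",
    "x",
    "y",
    "gene_id",
    "control_type",
    "signal_cy3",
    "signal_cy5",
]


@dataclass
class SimulationParams:
    """Generative parameters for one simulated experiment.

    baseline and tau are per-gene log2 quantities; tau has one column per
    stage.  SDs and effects are in log2 units; control signals are raw.
    """

    n_genes: int
    baseline: np.ndarray
    tau: np.ndarray
    dye_effect: float = 0.0
    array_sd: float = 0.0
    noise_sd: float = 0.0
    spatial_bias: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    intensity_bias: Callable[[np.ndarray], np.ndarray] | None = None
    control_mean: float = 100.0
    control_sd: float = 15.0
    n_controls_per_array: int = 200
    grid: tuple[int, int, int] | None = None  # (n_subgrids, rows, cols)
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.baseline.shape != (self.n_genes,):
            raise ValueError("baseline must have one entry per gene")
        if self.tau.shape[0] != self.n_genes:
            raise ValueError("tau must have one row per gene")
        for name in ("array_sd", "noise_sd", "control_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.grid is None:
            # 4 spatially separated subgrids per slide, square-ish, sized to fit
            per = -(-(self.n_genes + self.n_controls_per_array) // 4)
            rows = int(np.ceil(np.sqrt(per)))
            cols = -(-per // rows)
            self.grid = (4, rows, cols)

    @property
    def n_stages(self) -> int:
        return self.tau.shape[1]


def default_params(
    design: LoopDesign,
    n_genes: int = 6857,
    seed: int = 0,
    *,
    baseline_mean: float = 9.5,
    baseline_sd: float = 2.0,
    tau: np.ndarray | None = None,
    **overrides,
) -> SimulationParams:
    """Study-scale defaults: ~7k genes, realistic array/dye/noise magnitudes.

    Per-gene baselines are drawn once from N(baseline_mean, baseline_sd^2) on
    the log2 scale, which puts a few percent of genes below the non-specific
    background so the detection filter has real work to do.
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    if tau is None:
        tau = np.zeros((n_genes, design.n_stages))
    params = dict(
        n_genes=n_genes,
        baseline=baseline,
        tau=tau,
        dye_effect=0.3,
        array_sd=0.3,
        noise_sd=0.25,
        seed=seed,
    )
    params.update(overrides)
    return SimulationParams(**params)


def peaked_tau(
    n_genes: int,
    n_stages: int,
    peak_stages: list[list[int]],
    amplitude: float = 2.0,
    width: float = 1.0,
) -> np.ndarray:
    """Trajectories built from Gaussian bumps at the requested peak stages."""
    if len(peak_stages) != n_genes:
        raise ValueError("one peak-stage list per gene required")
    stages = np.arange(1, n_stages + 1, dtype=float)
    tau = np.zeros((n_genes, n_stages))
    for g, peaks in enumerate(peak_stages):
        for p in peaks:
            tau[g] += amplitude * np.exp(-0.5 * ((stages - p) / width) ** 2)
    return tau


def _spot_layout(params: SimulationParams) -> pd.DataFrame:
    """Deterministic spot positions: genes and controls interleaved on the grid.

    Controls are spread evenly through the print order so every subgrid sees
    background spots.  x/y are slide coordinates with the subgrids tiled two
    per row.
    """
    n_sub, rows, cols = params.grid
    n_spots = params.n_genes + params.n_controls_per_array
    if n_spots > n_sub * rows * cols:
        raise LayoutError(
            f"grid capacity {n_sub * rows * cols} < {n_spots} spots required"
        )
    labels = np.array([f"g{i:04d}" for i in range(params.n_genes)], dtype=object)
    control = np.zeros(n_spots, dtype=bool)
    if params.n_controls_per_array:
        idx = np.linspace(0, n_spots - 1, params.n_controls_per_array).astype(int)
        idx = np.unique(idx)
        # linspace collisions only at tiny sizes; pad from the tail
        extra = np.setdiff1d(np.arange(n_spots)[::-1], idx)[
            : params.n_controls_per_array - idx.size
        ]
        control[np.concatenate([idx, extra]).astype(int)] = True
    gene_id = np.empty(n_spots, dtype=object)
    gene_id[~control] = labels
    gene_id[control] = [f"hs{i:03d}" for i in range(int(control.sum()))]
    pos = np.arange(n_spots)
    subgrid = pos // (rows * cols)
    within = pos % (rows * cols)
    row = within // cols
    col = within % cols
    x = (subgrid % 2) * cols + col
    y = (subgrid // 2) * rows + row
    return pd.DataFrame(
        {
            "subgrid": subgrid + 1,
            "row": row + 1,
            "col": col + 1,
            "x": x.astype(float),
            "y": y.astype(float),
            "gene_id": gene_id,
            "control_type": np.where(control, "herring_sperm", ""),
        }
    )


def simulate_experiment(
    design: LoopDesign, params: SimulationParams
) -> tuple[list[pd.DataFrame], dict]:
    """Generate one spot table per array plus the truth record.

    Identical design + params (including seed) give bit-identical output.
    """
    if params.tau.shape[1] != design.n_stages:
        raise ValueError("tau must have one column per design stage")
    rng = np.random.default_rng(params.seed)
    layout = _spot_layout(params)
    is_gene = layout["control_type"].to_numpy() == ""
    gx = layout.loc[is_gene, "x"].to_numpy()
    gy = layout.loc[is_gene, "y"].to_numpy()
    b_field = (
        params.spatial_bias(gx, gy) if params.spatial_bias is not None else 0.0
    )

    array_effects = rng.normal(0.0, params.array_sd, size=design.n_arrays)
    tables: list[pd.DataFrame] = []
    for arr, a_eff in zip(design.arrays, array_effects):
        tab = layout.copy()
        tab.insert(0, "array_id", arr.array_id)
        signals = {}
        for dye, pool in (("Cy3", arr.cy3_pool), ("Cy5", arr.cy5_pool)):
            sign = 1.0 if dye == "Cy5" else -1.0
            log2sig = (
                params.baseline
                + params.tau[:, pool.stage - 1]
                + params.dye_effect * (dye == "Cy5")
                + a_eff
            )
            if params.intensity_bias is not None:
                log2sig = log2sig + params.intensity_bias(
                    params.baseline + params.tau[:, pool.stage - 1] + a_eff
                ) * sign / 2.0
            log2sig = log2sig + np.asarray(b_field) * sign
            log2sig = log2sig + rng.normal(0.0, params.noise_sd, size=params.n_genes)
            raw = np.zeros(len(tab))
            raw[is_gene] = 2.0**log2sig
            ctrl = rng.normal(
                params.control_mean, params.control_sd, size=int((~is_gene).sum())
            )
            raw[~is_gene] = np.clip(ctrl, 0.0, None)
            signals[dye] = raw
        tab["signal_cy3"] = signals["Cy3"]
        tab["signal_cy5"] = signals["Cy5"]
        tables.append(tab[SPOT_COLUMNS])

    gene_ids = layout.loc[is_gene, "gene_id"].to_numpy()
    truth = {
        "gene_id": gene_ids,
        "baseline": params.baseline.copy(),
        "tau": pd.DataFrame(
            params.tau,
            index=gene_ids,
            columns=[f"stage_{k}" for k in range(1, design.n_stages + 1)],
        ),
        "dye_effect": params.dye_effect,
        "array_effects": pd.Series(
            array_effects, index=[a.array_id for a in design.arrays]
        ),
    }
    return tables, truth
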