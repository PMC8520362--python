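"""Reference phantom studies: canned end-to-end experiments used to
characterize the pipeline (reconstruction accuracy, noise robustness, and
the statistical harness calibration).

Each study is a deterministic function of its seed and runs the public
pipeline exactly as a user would: phantom -> cloud -> reconstruction ->
morphometry -> statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .kernels import KernelSpec
from .morphometry import IntensityModel, MorphometryConfig, measure_complex
from .phantom import PhantomSpec, make_phantom, rasterize_truth, sample_cloud
from .reconstruct import (
    default_bandwidth,
    nearest_neighbor_baseline,
    psnr,
    reconstruct_volume,
)
from .regression import KernelRegression3D
from .stats import simulate_two_group_study, t_from_raw

__all__ = [
    "end_to_end_thickness_study",
    "psnr_comparison_study",
    "polynomial_reproduction_sweep",
    "type_i_error_study",
    "power_study",
]


def end_to_end_thickness_study(
    n: int = 200_000,
    spacing: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 1,
    order: int = 1,
) -> pd.DataFrame:
    """Full pipeline on the default phantom; per-site thickness errors.

    Samples ``n`` points, reconstructs at ``spacing`` mm with the automatic
    bandwidth, runs the 18-site protocol and returns the measurement table
    with ``expected_mm`` and ``error_mm`` columns against the analytic
    ground truth.
    """
    spec = PhantomSpec(seed=seed)
    truth = make_phantom(spec)
    cloud = sample_cloud(truth, n=n, noise_sd=noise_sd, seed=seed)
    grid = VoxelGrid.from_box(*spec.box, spacing)
    kspec = KernelSpec(bandwidth_h=default_bandwidth(cloud), order_N=order)
    vol, _ = reconstruct_volume(cloud, grid, kspec)
    table = measure_complex(
        vol, MorphometryConfig(intensity_model=IntensityModel(levels=spec.intensities))
    )
    expected = {
        (s, p, c): th for s, p, c, th in truth.thickness_table()
    }
    table["expected_mm"] = [
        expected[(r.structure, r.plane, r.clock)] for r in table.itertuples()
    ]
    table["error_mm"] = table["thickness_mm"] - table["expected_mm"]
    return table


def psnr_comparison_study(
    n: int = 200_000,
    spacing: float = 0.5,
    noise_sd: float = 10.0,
    seed: int = 1,
    orders: tuple = (0, 1, 2),
) -> dict:
    """Reconstruction quality versus the nearest-neighbor baseline.

    Returns ``{"kernel": {order: PSNR_dB}, "nearest": PSNR_dB}`` against the
    rasterized noiseless ground truth, on the same noisy cloud.
    """
    spec = PhantomSpec(seed=seed)
    truth = make_phantom(spec)
    cloud = sample_cloud(truth, n=n, noise_sd=noise_sd, seed=seed)
    grid = VoxelGrid.from_box(*spec.box, spacing)
    reference = rasterize_truth(truth, grid)
    rng = spec.intensity_range
    nn = nearest_neighbor_baseline(cloud, grid)
    out = {"kernel": {}, "nearest": psnr(nn, reference, rng)}
    h = default_bandwidth(cloud)
    for order in orders:
        vol, _ = reconstruct_volume(cloud, grid, KernelSpec(bandwidth_h=h, order_N=order))
        out["kernel"][order] = psnr(vol, reference, rng)
    return out


def polynomial_reproduction_sweep(n_configs: int = 50, seed: int = 0) -> float:
    """Worst relative error reconstructing degree-<=N fields at orders 0/1/2.

    Each configuration draws a random polynomial of the matching degree,
    a random cloud, bandwidth and query points; exactness of the local
    polynomial fit makes the error roundoff-level.  Returns the maximum
    relative error across all configurations.
    """
    worst = 0.0
    rng_master = np.random.default_rng(seed)
    for _ in range(n_configs):
        cfg_seed = int(rng_master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(cfg_seed)
        order = int(rng.integers(0, 3))
        c0 = rng.normal()
        lin = rng.normal(size=3) if order >= 1 else np.zeros(3)
        quad = rng.normal(size=(3, 3)) if order >= 2 else np.zeros((3, 3))
        quad = (quad + quad.T) / 2

        def f(p):
            p = np.atleast_2d(p)
            return c0 + p @ lin + np.einsum("ni,ij,nj->n", p, quad, p)

        X = rng.uniform(-1, 1, size=(300, 3))
        y = f(X)
        h = float(rng.uniform(0.3, 1.0))
        model = KernelRegression3D(bandwidth=h, order=order).fit(X, y)
        q = rng.uniform(-0.5, 0.5, size=(5, 3))
        scale = max(1.0, float(np.abs(y).max()))
        err = float(np.max(np.abs(model.predict(q) - f(q)))) / scale
        worst = max(worst, err)
    return worst


def type_i_error_study(
    replicates: int = 2000, n1: int = 77, n2: int = 80, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical false-positive rate of the harness under a null effect."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        tabs = simulate_two_group_study(
            {"null": (2.0, 0.5, 2.0, 0.5)}, n1, n2, seed=int(rng.integers(0, 2**31 - 1))
        )
        hits += t_from_raw(*tabs["null"]).p < alpha
    return hits / replicates


def power_study(
    replicates: int = 1000,
    effect: tuple = (1.04, 0.27, 1.87, 0.55),
    n1: int = 77,
    n2: int = 80,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical detection rate at a given (mean1, sd1, mean2, sd2) effect.

    The default effect is the largest wall-thickness difference in the
    reference study (EAS, distal plane, 12 o'clock).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        tabs = simulate_two_group_study(
            {"site": effect}, n1, n2, seed=int(rng.integers(0, 2**31 - 1))
        )
        hits += t_from_raw(*tabs["site"]).p < alpha
    return hits / replicates
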