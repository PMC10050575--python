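"""Shared fixtures: small meshes, montages, lead fields, and the (expensive,
session-scoped) multi-seed benchmark sweep reused by several tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
import scipy.sparse as sp

from cesi import (
    ScenarioSpec,
    SolverConfig,
    apply_operator,
    build_benchmark,
    emd,
    make_scalp_montage,
    make_sphere_source_space,
    make_toy_leadfield,
    slcmv_operator,
    smne_operator,
    sssbl_solve,
)
from cesi.spectral import band_average


@pytest.fixture(scope="session")
def small_space():
    """40-vertex spherical source mesh (80 mm) with geodesics precomputed."""
    space = make_sphere_source_space(40, 80.0)
    space.geodesic  # warm the cache once per session
    return space


@pytest.fixture(scope="session")
def montage():
    return make_scalp_montage(19, 100.0)


@pytest.fixture(scope="session")
def small_leadfield(montage, small_space):
    return make_toy_leadfield(montage, small_space)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_hop_neighbors(space) -> np.ndarray:
    """Boolean (G, G) matrix: within two mesh edges."""
    t = space.triangles
    g = space.num_vertices
    adj = sp.coo_matrix(
        (
            np.ones(3 * len(t)),
            (np.r_[t[:, 0], t[:, 1], t[:, 2]], np.r_[t[:, 1], t[:, 2], t[:, 0]]),
        ),
        shape=(g, g),
    )
    adj = ((adj + adj.T) > 0).astype(int)
    reach = (adj @ adj + adj).toarray() > 0
    np.fill_diagonal(reach, True)
    return reach


@pytest.fixture(scope="session")
def benchmark_sweep():
    """ssSBL vs baselines on the default scenario over 20 seeds.

    Returns one record per seed with the CST-truth correlations of ssSBL
    and sMNE (pooled over bands), mean EMDs of ssSBL and sLCMV, and the
    per-patch support-recovery indicator (top-3 gamma within the 2-hop
    neighborhood of each patch center in its own band).
    """
    base = ScenarioSpec()
    records = []
    reach = None
    for seed in range(1, 21):
        spec = replace(base, seed=seed)
        bundle = build_benchmark(spec)
        if reach is None:
            reach = two_hop_neighbors(bundle.space)
        lf = bundle.leadfield
        truth = band_average(bundle.source_cs, spec.bands).diagonal()
        bands = band_average(bundle.source_cs, spec.bands).band_names
        freqs = bundle.grid.frequencies

        _, state, src = sssbl_solve(bundle.sensor_cs, lf, SolverConfig())
        est_ss = band_average(src, spec.bands).diagonal()

        alpha_eff = 1e-2 * float(
            np.trace(lf.matrix @ lf.matrix.T) / lf.num_sensors
        )
        op = smne_operator(lf, alpha=alpha_eff)
        est_mn = band_average(apply_operator(op, bundle.sensor_cs), spec.bands).diagonal()

        sens_band = band_average(bundle.sensor_cs, spec.bands)
        bf_ops = slcmv_operator(lf, sens_band)
        est_bf = apply_operator(bf_ops, sens_band).diagonal()

        dist = bundle.space.geodesic
        corr = lambda est: float(np.corrcoef(est.ravel(), truth.ravel())[0, 1])
        support_ok = True
        for p in spec.patches:
            lo, hi = spec.bands[p.band]
            mask = (freqs >= lo) & (freqs < hi)
            g_band = state.gamma[mask].mean(axis=0)
            top = np.argsort(-g_band)[: len(spec.patches)]
            if not reach[p.center, top].any():
                support_ok = False
        records.append(
            {
                "seed": seed,
                "corr_sssbl": corr(est_ss),
                "corr_smne": corr(est_mn),
                "emd_sssbl": float(
                    np.mean([emd(est_ss[i], truth[i], dist) for i in range(len(bands))])
                ),
                "emd_slcmv": float(
                    np.mean([emd(est_bf[i], truth[i], dist) for i in range(len(bands))])
                ),
                "support_ok": support_ok,
            }
        )
    return records
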