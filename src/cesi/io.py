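"""File formats: OFF meshes, CSV montages and time series, HDF5 containers.

Write/read round-trips are lossless for exact fields and to near machine
precision for floating payloads.  Cross-spectrum containers are validated
(Hermitian PSD invariants) at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from cesi.forward import LeadField, SensorMontage, SourceSpace
from cesi.spectral import CrossSpectrum, SpectralGrid

__all__ = [
    "write_mesh_off",
    "read_mesh_off",
    "write_montage_csv",
    "read_montage_csv",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_leadfield_h5",
    "read_leadfield_h5",
    "write_cross_spectrum_h5",
    "read_cross_spectrum_h5",
    "write_solver_result_h5",
    "read_solver_result_h5",
]


def write_mesh_off(space: SourceSpace, path: str | Path) -> None:
    """OFF-style text mesh: vertex/triangle counts, coordinates, index triples."""
    lines = ["OFF", f"{space.num_vertices} {len(space.triangles)} 0"]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in space.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in space.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_off(path: str | Path) -> SourceSpace:
    tokens = Path(path).read_text().split()
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file (missing header)")
    try:
        nv, nt = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        tris = np.empty((nt, 3), dtype=int)
        for i in range(nt):
            cnt = int(tokens[pos])
            if cnt != 3:
                raise ValueError(f"{path}: face {i} has {cnt} vertices, expected 3")
            tris[i] = [int(t) for t in tokens[pos + 1 : pos + 4]]
            pos += 4
    except (IndexError, ValueError) as exc:
        if "face" in str(exc):
            raise
        raise ValueError(f"{path}: malformed OFF file ({exc})") from exc
    if tris.size and (tris.min() < 0 or tris.max() >= nv):
        raise ValueError(f"{path}: triangle index out of range [0, {nv})")
    return SourceSpace(verts, tris)


def write_montage_csv(montage: SensorMontage, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": montage.names,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
        }
    ).to_csv(path, index=False)


def read_montage_csv(path: str | Path) -> SensorMontage:
    df = pd.read_csv(path)
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: montage CSV missing columns {sorted(missing)}")
    return SensorMontage(
        [str(n) for n in df["name"]], df[["x", "y", "z"]].to_numpy(dtype=float)
    )


def write_timeseries_csv(
    data: np.ndarray, channel_names: list[str], path: str | Path
) -> None:
    """Channels-by-samples array stored column-per-channel with a header row."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] != len(channel_names):
        raise ValueError("channel_names length does not match rows of data")
    pd.DataFrame(data.T, columns=channel_names).to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty time-series file")
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns]


def write_leadfield_h5(lf: LeadField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=lf.matrix)
        f.create_dataset(
            "channel_names",
            data=np.array(lf.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["source_space_id"] = lf.source_space_id
        f.attrs["metadata"] = json.dumps(lf.metadata)


def read_leadfield_h5(path: str | Path) -> LeadField:
    with h5py.File(path, "r") as f:
        return LeadField(
            f["matrix"][()],
            [n.decode() if isinstance(n, bytes) else str(n) for n in f["channel_names"][()]],
            source_space_id=str(f.attrs.get("source_space_id", "")),
            metadata=json.loads(f.attrs.get("metadata", "{}")),
        )


def _write_grid(f: h5py.File, grid: SpectralGrid) -> None:
    f.create_dataset("frequencies", data=grid.frequencies)
    f.attrs["num_samples_per_segment"] = grid.num_samples_per_segment
    f.attrs["sampling_period"] = grid.sampling_period
    f.attrs["num_segments"] = grid.num_segments


def _read_grid(f: h5py.File) -> SpectralGrid:
    return SpectralGrid(
        int(f.attrs["num_samples_per_segment"]),
        float(f.attrs["sampling_period"]),
        f["frequencies"][()],
        int(f.attrs["num_segments"]),
    )


def write_cross_spectrum_h5(cs: CrossSpectrum, path: str | Path) -> None:
    """Binary container: per-frequency complex matrices plus grid metadata.

    The per-frequency diagonal can be mirrored to CSV with
    :func:`write_spectrum_csv`.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices_real", data=cs.matrices.real)
        f.create_dataset("matrices_imag", data=cs.matrices.imag)
        _write_grid(f, cs.grid)
        f.attrs["sample_size"] = cs.sample_size
        f.attrs["space_tag"] = cs.space_tag
        if cs.band_names is not None:
            f.attrs["band_names"] = json.dumps(list(cs.band_names))


def read_cross_spectrum_h5(path: str | Path) -> CrossSpectrum:
    with h5py.File(path, "r") as f:
        mats = f["matrices_real"][()] + 1j * f["matrices_imag"][()]
        bn = f.attrs.get("band_names")
        return CrossSpectrum(
            mats,
            int(f.attrs["sample_size"]),
            _read_grid(f),
            space_tag=str(f.attrs["space_tag"]),
            band_names=tuple(json.loads(bn)) if bn is not None else None,
        )


def write_spectrum_csv(cs: CrossSpectrum, path: str | Path) -> None:
    """CSV export of the per-frequency diagonal (rows: frequency/band)."""
    index = (
        list(cs.band_names)
        if cs.band_names is not None
        else [f"{f:.6g}" for f in cs.grid.frequencies]
    )
    pd.DataFrame(cs.diagonal(), index=index).to_csv(path, index_label="frequency")


def write_solver_result_h5(ops, state, config, path: str | Path) -> None:
    """Serialize per-frequency operators plus ssSBL state and config echo."""
    with h5py.File(path, "w") as f:
        f.create_dataset("T", data=np.stack([op.T for op in ops]))
        pis = [op.Pi for op in ops]
        if all(p is not None for p in pis):
            f.create_dataset("Pi", data=np.stack(pis))
        f.attrs["method"] = ops[0].method
        f.attrs["frequencies"] = json.dumps([str(op.frequency) for op in ops])
        if state is not None:
            f.create_dataset("gamma", data=state.gamma)
            f.create_dataset("beta", data=state.beta)
            grp = f.create_group("objective_trace")
            for k, tr in enumerate(state.objective_trace):
                grp.create_dataset(str(k), data=tr)
        if config is not None:
            f.attrs["config"] = json.dumps(
                {k: v for k, v in vars(config).items() if np.isscalar(v) or v is None}
            )


def read_solver_result_h5(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        out = {
            "T": f["T"][()],
            "method": str(f.attrs["method"]),
            "frequencies": json.loads(f.attrs["frequencies"]),
        }
        if "Pi" in f:
            out["Pi"] = f["Pi"][()]
        if "gamma" in f:
            out["gamma"] = f["gamma"][()]
            out["beta"] = f["beta"][()]
            out["objective_trace"] = [
                f["objective_trace"][k][()]
                for k in sorted(f["objective_trace"], key=int)
            ]
        if "config" in f.attrs:
            out["config"] = json.loads(f.attrs["config"])
        return out
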