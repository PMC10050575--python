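"""Synthetic benchmark generators.

Everything the rest of the package consumes can be generated here: a
spherical cortical mesh with geodesic distances, a scalp montage, a toy
lead field, band-structured ground-truth source cross-spectra built as a
dense smooth background plus sparse coherent patches, circularly symmetric
complex Gaussian Fourier instances, stationary AR(2) oscillator time
series with known analytic spectra, and fully assembled benchmark bundles.

The default scenario emulates a low-density recording: E = 19 sensors on a
100 mm scalp sphere, G = 200 sources on an 80 mm cortical sphere, M = 600
segments, three coherent patches (theta, alpha, beta) of 15 mm geodesic
radius over a weak spatially smooth incoherent background, and sensor
noise at 10 dB SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.spatial import ConvexHull

from cesi.forward import (
    LeadField,
    SensorMontage,
    SourceSpace,
    make_toy_leadfield,
    project_source_cross_spectrum,
)
from cesi.spectral import DEFAULT_BANDS, CrossSpectrum, FourierInstances, SpectralGrid

__all__ = [
    "PatchSpec",
    "ScenarioSpec",
    "SyntheticBundle",
    "make_sphere_source_space",
    "make_scalp_montage",
    "make_source_cross_spectrum",
    "sample_fourier_instances",
    "make_oscillator_series",
    "ar2_spectral_density",
    "build_benchmark",
]

DEFAULT_SEED = 20230315


def _fibonacci_points(n: int, zmin: float = -1.0, zmax: float = 1.0) -> np.ndarray:
    """Deterministic near-uniform points on a spherical zone via the golden spiral."""
    i = np.arange(n) + 0.5
    z = zmax - (zmax - zmin) * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_sphere_source_space(num_sources: int = 200, radius: float = 80.0) -> SourceSpace:
    """Triangulated sphere with exactly ``num_sources`` vertices (mm).

    Vertices follow a Fibonacci spiral; triangles come from the convex hull
    and are oriented outward, so vertex normals point radially.
    """
    if num_sources < 4:
        raise ValueError("need at least 4 vertices for a closed mesh")
    pts = _fibonacci_points(num_sources) * radius
    hull = ConvexHull(pts)
    tri = hull.simplices.copy()
    # orient each triangle so its normal points away from the origin
    v = pts
    normals = np.cross(v[tri[:, 1]] - v[tri[:, 0]], v[tri[:, 2]] - v[tri[:, 0]])
    centers = v[tri].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centers) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return SourceSpace(pts, tri)


def make_scalp_montage(num_sensors: int = 19, radius: float = 100.0) -> SensorMontage:
    """Sensors spread over the upper scalp (spherical cap z/r > 0.05)."""
    pts = _fibonacci_points(num_sensors, zmin=0.05, zmax=0.95) * radius
    names = [f"E{i + 1:02d}" for i in range(num_sensors)]
    return SensorMontage(names, pts)


@dataclass(frozen=True)
class PatchSpec:
    """One coherent cortical patch: center vertex, geodesic radius (mm),
    band tag, and rank-1 power."""

    center: int
    radius_mm: float = 15.0
    band: str = "alpha"
    power: float = 1.0


@dataclass
class ScenarioSpec:
    """Full description of a synthetic benchmark scenario.

    ``noise_power`` of ``None`` means the sensor-noise variance is derived
    at build time from ``snr_db`` (signal-to-noise ratio of mean sensor
    power).  All randomness is driven by ``seed``.
    """

    num_sensors: int = 19
    num_sources: int = 200
    num_segments: int = 600
    # None selects three default patches whose centers lie under the sensor
    # cap (upper hemisphere of the Fibonacci ordering, at fixed fractions of
    # the vertex count) so the activity is visible to a scalp montage
    patches: tuple[PatchSpec, ...] | None = None
    background_power: float = 0.01
    noise_power: float | None = None
    snr_db: float = 10.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    sampling_rate: float = 200.0
    num_samples_per_segment: int = 201
    fmin: float = 1.0
    fmax: float = 45.0
    source_radius: float = 80.0
    sensor_radius: float = 100.0
    background_smoothness_mm: float = 30.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.num_sensors >= self.num_sources:
            raise ValueError("the intended regime has fewer sensors than sources")
        if self.patches is None:
            g = self.num_sources
            self.patches = (
                PatchSpec(center=round(0.10 * g), band="theta"),
                PatchSpec(center=round(0.225 * g), band="alpha"),
                PatchSpec(center=round(0.35 * g), band="beta"),
            )
        if self.background_power < 0:
            raise ValueError("background_power must be nonnegative")
        if self.noise_power is not None and self.noise_power < 0:
            raise ValueError("noise_power must be nonnegative")
        for p in self.patches:
            if not 0 <= p.center < self.num_sources:
                raise ValueError(f"patch center {p.center} is not a valid vertex")
            if p.power < 0:
                raise ValueError("patch power must be nonnegative")
            if p.band not in self.bands:
                raise ValueError(f"patch band {p.band!r} is not a named band")

    def grid(self) -> SpectralGrid:
        return SpectralGrid.from_band(
            self.num_samples_per_segment,
            self.sampling_rate,
            self.num_segments,
            fmin=self.fmin,
            fmax=self.fmax,
        )


def _band_shape(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Unit-peak Hann-shaped spectral profile supported on [lo, hi)."""
    shape = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs < hi)
    shape[inside] = np.sin(np.pi * (freqs[inside] - lo) / (hi - lo)) ** 2
    return shape


def make_source_cross_spectrum(
    spec: ScenarioSpec, space: SourceSpace, grid: SpectralGrid | None = None
) -> CrossSpectrum:
    """Ground-truth source cross-spectrum: smooth background + coherent patches.

    Per frequency the matrix is a diagonal incoherent background (power
    ``background_power`` scaled by a geodesically smooth positive field,
    flat across frequency) plus, for each patch, a rank-1 coherent term
    ``power * shape(f) * u u^T`` where ``u`` is a geodesic Gaussian bump of
    the patch radius centered at the patch vertex and ``shape`` is a
    unit-peak profile supported in the patch's band.
    """
    grid = grid or spec.grid()
    g = space.num_vertices
    if g != spec.num_sources:
        raise ValueError("source space size does not match the scenario")
    dist = space.geodesic
    diam = float(dist.max())
    for p in spec.patches:
        if p.radius_mm > diam:
            raise ValueError(
                f"patch radius {p.radius_mm} mm exceeds the mesh diameter {diam:.1f} mm"
            )
    rng = np.random.default_rng(spec.seed)
    freqs = grid.frequencies
    nf = freqs.size

    mats = np.zeros((nf, g, g), dtype=complex)
    if spec.background_power > 0:
        ell = spec.background_smoothness_mm
        kernel = np.exp(-0.5 * (dist / ell) ** 2)
        fld = kernel @ np.abs(rng.standard_normal(g))
        fld = fld / fld.mean()
        bg = spec.background_power * fld
        mats[:, np.arange(g), np.arange(g)] = bg[None, :]

    for p in spec.patches:
        u = np.exp(-0.5 * (dist[:, p.center] / p.radius_mm) ** 2)
        shape = _band_shape(freqs, *spec.bands[p.band])
        mats += p.power * shape[:, None, None] * np.outer(u, u)[None, :, :]

    return CrossSpectrum(mats, spec.num_segments, grid, space_tag="source")


def sample_fourier_instances(
    cs: CrossSpectrum, M: int, seed: int | np.random.Generator = DEFAULT_SEED
) -> FourierInstances:
    """Draw M circularly symmetric complex Gaussian instances per frequency.

    ``x = Sigma^{1/2} (z_re + i z_im) / sqrt(2)`` with standard normal z,
    so ``E[x x^H] = Sigma`` and the pseudo-covariance ``E[x x^T]`` vanishes.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    r = cs.num_channels
    nf = cs.grid.num_frequencies
    out = np.zeros((M, r, nf), dtype=complex)
    for k, mat in enumerate(cs.matrices):
        w, v = np.linalg.eigh(0.5 * (mat + mat.conj().T))
        if w[0] < -1e-8 * max(w[-1], 0.0):
            raise ValueError(f"matrix at frequency index {k} is not PSD")
        root = v * np.sqrt(np.maximum(w, 0.0))
        z = rng.standard_normal((M, r)) + 1j * rng.standard_normal((M, r))
        out[:, :, k] = (z / np.sqrt(2.0)) @ root.T  # rows x_m = root z_m
    grid = cs.grid
    if grid.num_segments != M:
        from dataclasses import replace

        grid = replace(grid, num_segments=M)
    return FourierInstances(out, grid)


def make_oscillator_series(
    num_channels: int,
    ar_params: list[tuple[float, float]] | tuple[float, float],
    length: int,
    seed: int = DEFAULT_SEED,
    innovation_sd: float = 1.0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Stationary Gaussian AR(2) oscillator realizations, (channels, length).

    Each channel follows ``x_t = a1 x_{t-1} + a2 x_{t-2} + eps_t`` with
    i.i.d. Gaussian innovations; parameters must be stationary (AR roots
    inside the unit circle).  The analytic spectral density is available
    from :func:`ar2_spectral_density`.
    """
    if isinstance(ar_params, tuple) and np.isscalar(ar_params[0]):
        ar_params = [tuple(ar_params)] * num_channels
    if len(ar_params) != num_channels:
        raise ValueError("need one (a1, a2) pair per channel")
    for a1, a2 in ar_params:
        roots = np.roots([1.0, -a1, -a2])
        if np.any(np.abs(roots) >= 1.0 - 1e-10):
            raise ValueError(f"AR parameters ({a1}, {a2}) are not stationary")
    rng = np.random.default_rng(seed)
    out = np.empty((num_channels, length))
    for ch, (a1, a2) in enumerate(ar_params):
        eps = innovation_sd * rng.standard_normal(length + burn_in)
        x = lfilter([1.0], [1.0, -a1, -a2], eps)
        out[ch] = x[burn_in:]
    return out


def ar2_spectral_density(
    a1: float, a2: float, freqs: np.ndarray, sampling_rate: float,
    innovation_sd: float = 1.0,
) -> np.ndarray:
    """Discrete-time AR(2) spectral density sigma^2 / |1 - a1 e^{-iw} - a2 e^{-2iw}|^2.

    ``w = 2 pi f / fs``.  Under the centered DFT convention of this
    package, the sample cross-spectrum of raw (unnormalized) Fourier
    coefficients converges to ``n * S(f)`` for segments of length ``n``.
    """
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float) / sampling_rate
    denom = np.abs(1.0 - a1 * np.exp(-1j * w) - a2 * np.exp(-2j * w)) ** 2
    return innovation_sd**2 / denom


@dataclass
class SyntheticBundle:
    """Everything needed to run and score a solver on one scenario."""

    spec: ScenarioSpec
    space: SourceSpace
    montage: SensorMontage
    leadfield: LeadField
    grid: SpectralGrid
    source_cs: CrossSpectrum
    noise_cs: CrossSpectrum
    sensor_cs_analytic: CrossSpectrum
    instances: FourierInstances
    sensor_cs: CrossSpectrum
    truth_cst: np.ndarray
    noise_power: float


def build_benchmark(spec: ScenarioSpec | None = None) -> SyntheticBundle:
    """Assemble the full synthetic benchmark for a scenario.

    Pipeline: ground-truth source cross-spectrum -> analytic sensor
    cross-spectrum ``L Sigma_ii L^T + Sigma_xi`` -> M sampled sensor
    Fourier instances -> sample sensor cross-spectrum.  Deterministic for a
    fixed seed.
    """
    from cesi.spectral import sample_cross_spectrum

    spec = spec or ScenarioSpec()
    space = make_sphere_source_space(spec.num_sources, spec.source_radius)
    montage = make_scalp_montage(spec.num_sensors, spec.sensor_radius)
    lf = make_toy_leadfield(montage, space, source_space_id="fibonacci-sphere")
    grid = spec.grid()
    source_cs = make_source_cross_spectrum(spec, space, grid)

    e = spec.num_sensors
    signal_power = float(
        np.mean(
            [
                np.real(np.trace(lf.matrix @ m @ lf.matrix.T)) / e
                for m in source_cs.matrices
            ]
        )
    )
    if spec.noise_power is None:
        noise_power = signal_power / 10.0 ** (spec.snr_db / 10.0)
    else:
        noise_power = float(spec.noise_power)
    noise_mats = np.broadcast_to(
        noise_power * np.eye(e), (grid.num_frequencies, e, e)
    ).astype(complex)
    noise_cs = CrossSpectrum(noise_mats, spec.num_segments, grid, space_tag="sensor")

    sensor_analytic = project_source_cross_spectrum(source_cs, lf, noise_cs)
    instances = sample_fourier_instances(
        sensor_analytic, spec.num_segments, seed=spec.seed
    )
    sensor_cs = sample_cross_spectrum(instances, space_tag="sensor")
    return SyntheticBundle(
        spec=spec,
        space=space,
        montage=montage,
        leadfield=lf,
        grid=grid,
        source_cs=source_cs,
        noise_cs=noise_cs,
        sensor_cs_analytic=sensor_analytic,
        instances=instances,
        sensor_cs=sensor_cs,
        truth_cst=source_cs.diagonal(),
        noise_power=noise_power,
    )
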