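"""Frequency-domain estimation and probability machinery.

Implements the estimation pipeline from raw multichannel time series to
per-frequency cross-spectral matrices: segmentation, a centered discrete
Fourier transform, segment-averaged sample cross-spectra, the circularly
symmetric complex Gaussian density of Fourier coefficients, the complex
Wishart log-likelihood of sample cross-spectra, a per-coefficient
Gaussianity test, and aggregation into named frequency bands.

Conventions
-----------
The DFT of a segment of odd length ``2T + 1`` runs over the centered time
index ``t = -T .. T``::

    x(f) = sum_{t=-T}^{T} x(t) exp(-i 2 pi (f dnu) (t dsigma))

with spectral resolution ``dnu = 1 / ((2T + 1) dsigma)``, so the exponent
reduces to ``-i 2 pi f t / (2T + 1)`` on the integer frequency index ``f``.
No taper is applied by default; a Hann taper is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_BANDS",
    "SpectralGrid",
    "FourierInstances",
    "CrossSpectrum",
    "GaussianityResult",
    "segment_time_series",
    "discrete_fourier_transform",
    "fourier_instances",
    "sample_cross_spectrum",
    "complex_gaussian_logdensity",
    "complex_wishart_loglik",
    "gaussianity_test",
    "band_average",
]

#: Conventional EEG band edges in Hz, closed-open intervals.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

_HERMITIAN_RTOL = 1e-10
_PSD_RTOL = 1e-8


@dataclass(frozen=True)
class SpectralGrid:
    """Discrete frequency grid tied to a segmentation scheme.

    Parameters
    ----------
    num_samples_per_segment
        Odd segment length ``2T + 1``.
    sampling_period
        Sampling period in seconds.
    frequencies
        Strictly increasing nonnegative frequencies in Hz, each an integer
        multiple of the spectral resolution and at most the Nyquist
        frequency.
    num_segments
        Number of segments ``M`` averaged into the cross-spectrum.
    """

    num_samples_per_segment: int
    sampling_period: float
    frequencies: np.ndarray
    num_segments: int

    def __post_init__(self) -> None:
        n = int(self.num_samples_per_segment)
        if n < 3 or n % 2 != 1:
            raise ValueError(f"segment length must be odd and >= 3, got {n}")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.num_segments < 1:
            raise ValueError("num_segments must be >= 1")
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("frequencies must be a nonempty 1-D array")
        if np.any(freqs < 0) or np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be nonnegative, strictly increasing")
        nyquist = 0.5 / self.sampling_period
        if freqs[-1] > nyquist * (1 + 1e-12):
            raise ValueError("frequencies exceed the Nyquist frequency")

    @property
    def spectral_resolution(self) -> float:
        """Frequency spacing dnu = 1 / ((2T+1) dsigma) in Hz."""
        return 1.0 / (self.num_samples_per_segment * self.sampling_period)

    @property
    def frequency_indices(self) -> np.ndarray:
        """Integer DFT bin index of each grid frequency.

        Raises if any frequency is not an integer multiple of the spectral
        resolution (band-center grids produced by aggregation are valid
        containers but cannot index a DFT).
        """
        idx = self.frequencies / self.spectral_resolution
        if np.max(np.abs(idx - np.round(idx))) > 1e-6:
            raise ValueError(
                "frequencies are not integer multiples of the spectral resolution"
            )
        return np.round(idx).astype(int)

    @property
    def num_frequencies(self) -> int:
        return int(self.frequencies.size)

    @classmethod
    def from_band(
        cls,
        num_samples_per_segment: int,
        sampling_rate: float,
        num_segments: int,
        fmin: float = 0.0,
        fmax: float | None = None,
    ) -> "SpectralGrid":
        """Build a grid of all DFT frequencies within ``[fmin, fmax]``."""
        dt = 1.0 / sampling_rate
        dnu = 1.0 / (num_samples_per_segment * dt)
        nyq = 0.5 * sampling_rate
        if fmax is None:
            fmax = nyq
        kmax = num_samples_per_segment // 2
        freqs = np.arange(kmax + 1) * dnu
        mask = (freqs >= fmin - 1e-12) & (freqs <= min(fmax, nyq) + 1e-12)
        if not mask.any():
            raise ValueError("no grid frequencies inside the requested band")
        return cls(num_samples_per_segment, dt, freqs[mask], num_segments)


@dataclass(frozen=True)
class FourierInstances:
    """Complex Fourier coefficients, indexed (segment, channel, frequency)."""

    values: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=complex)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 3:
            raise ValueError("values must be (segments, channels, frequencies)")
        if vals.shape[0] != self.grid.num_segments:
            raise ValueError(
                f"segment count {vals.shape[0]} does not match "
                f"grid.num_segments {self.grid.num_segments}"
            )
        if vals.shape[2] != self.grid.num_frequencies:
            raise ValueError("frequency axis does not match the grid")

    @property
    def num_segments(self) -> int:
        return int(self.values.shape[0])

    @property
    def num_channels(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class CrossSpectrum:
    """Per-frequency Hermitian PSD cross-spectral matrices.

    ``matrices`` has shape (F, R, R); ``space_tag`` records whether the
    matrices live in sensor or source space.  ``band_names`` is set when the
    object is the result of band aggregation, in which case ``frequencies``
    in the grid hold band centers.
    """

    matrices: np.ndarray
    sample_size: int
    grid: SpectralGrid
    space_tag: str = "sensor"
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mats = np.asarray(self.matrices, dtype=complex)
        object.__setattr__(self, "matrices", mats)
        if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
            raise ValueError("matrices must have shape (F, R, R)")
        if mats.shape[0] != self.grid.num_frequencies:
            raise ValueError("matrix count does not match the grid")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.space_tag not in ("sensor", "source"):
            raise ValueError("space_tag must be 'sensor' or 'source'")
        self.validate()

    def validate(self) -> None:
        """Check Hermitianity, positive semidefiniteness, and diagonal."""
        for k, mat in enumerate(self.matrices):
            scale = float(np.abs(mat).max()) or 1.0
            if np.abs(mat - mat.conj().T).max() > _HERMITIAN_RTOL * scale:
                raise ValueError(f"matrix at frequency index {k} is not Hermitian")
            eig = np.linalg.eigvalsh(0.5 * (mat + mat.conj().T))
            if eig[0] < -_PSD_RTOL * max(eig[-1], 0.0) - 1e-300:
                raise ValueError(
                    f"matrix at frequency index {k} is not PSD "
                    f"(min eigenvalue {eig[0]:.3e})"
                )
            diag = np.diagonal(mat)
            if np.abs(diag.imag).max() > _HERMITIAN_RTOL * scale:
                raise ValueError(f"diagonal at frequency index {k} is not real")

    @property
    def num_channels(self) -> int:
        return int(self.matrices.shape[1])

    def diagonal(self) -> np.ndarray:
        """Real per-frequency diagonal (the spectral topography), (F, R)."""
        return np.real(np.diagonal(self.matrices, axis1=1, axis2=2)).copy()


def segment_time_series(
    data: np.ndarray, segment_length: int, overlap: int = 0
) -> list[np.ndarray]:
    """Split a channels-by-time array into overlapping segments.

    Returns ``floor((Ttot - overlap) / (segment_length - overlap))`` segments
    of shape (channels, segment_length); any trailing remainder is dropped.
    """
    data = np.atleast_2d(np.asarray(data))
    total = data.shape[1]
    if segment_length > total:
        raise ValueError(
            f"segment_length {segment_length} exceeds data length {total}"
        )
    if not 0 <= overlap < segment_length:
        raise ValueError("overlap must satisfy 0 <= overlap < segment_length")
    step = segment_length - overlap
    count = (total - overlap) // step
    return [data[:, m * step : m * step + segment_length].copy() for m in range(count)]


def _centered_dft(segment: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """DFT over the centered index t = -T..T at integer bins ``indices``."""
    n = segment.shape[-1]
    T = (n - 1) // 2
    full = np.fft.fft(segment, axis=-1)
    # fft sums over t = 0..n-1; shifting to t = -T..T multiplies bin k by
    # exp(+i 2 pi k T / n)
    phase = np.exp(2j * np.pi * indices * T / n)
    return full[..., indices] * phase


def discrete_fourier_transform(
    segment: np.ndarray, grid: SpectralGrid, taper: str = "none"
) -> np.ndarray:
    """Centered DFT of one segment, evaluated on the grid frequencies.

    Parameters
    ----------
    segment
        Real array (channels, 2T+1) or (2T+1,).
    grid
        Frequency grid; the segment length must match.
    taper
        ``"none"`` (default, plain DFT) or ``"hann"``.

    Returns
    -------
    Complex coefficients, shape (channels, F) (or (F,) for 1-D input).
    """
    seg = np.asarray(segment, dtype=float)
    squeeze = seg.ndim == 1
    seg = np.atleast_2d(seg)
    if seg.shape[-1] != grid.num_samples_per_segment:
        raise ValueError(
            f"segment length {seg.shape[-1]} does not match grid "
            f"({grid.num_samples_per_segment})"
        )
    if taper == "hann":
        seg = seg * np.hanning(seg.shape[-1])
    elif taper != "none":
        raise ValueError(f"unknown taper {taper!r}")
    out = _centered_dft(seg, grid.frequency_indices)
    return out[0] if squeeze else out


def fourier_instances(
    segments: list[np.ndarray] | np.ndarray,
    grid: SpectralGrid,
    taper: str = "none",
) -> FourierInstances:
    """Apply the centered DFT to every segment and stack the results."""
    segs = list(segments)
    if len(segs) != grid.num_segments:
        raise ValueError(
            f"got {len(segs)} segments but grid.num_segments is {grid.num_segments}"
        )
    coeffs = np.stack(
        [discrete_fourier_transform(s, grid, taper=taper) for s in segs]
    )
    return FourierInstances(coeffs, grid)


def sample_cross_spectrum(
    instances: FourierInstances, space_tag: str = "sensor"
) -> CrossSpectrum:
    """Segment-averaged sample cross-spectrum (1/M) sum_m v_m v_m^H."""
    vals = instances.values
    if vals.shape[0] < 1:
        raise ValueError("at least one Fourier instance is required")
    # (m, r, f), (m, s, f) -> (f, r, s)
    mats = np.einsum("mrf,msf->frs", vals, vals.conj()) / vals.shape[0]
    mats = 0.5 * (mats + np.conj(np.transpose(mats, (0, 2, 1))))
    return CrossSpectrum(mats, vals.shape[0], instances.grid, space_tag=space_tag)


def complex_gaussian_logdensity(x: np.ndarray, sigma: np.ndarray) -> float:
    """Log-density of the circularly symmetric complex Gaussian N_C(0, Sigma).

    ``-log|pi Sigma| - x^H Sigma^{-1} x`` for Hermitian positive definite
    ``Sigma``; integrates to one over C^R.
    """
    x = np.asarray(x, dtype=complex).ravel()
    sigma = np.asarray(sigma, dtype=complex)
    r = x.size
    if sigma.shape != (r, r):
        raise ValueError("sigma must be R x R matching x")
    try:
        c, low = cho_factor(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises own
        raise np.linalg.LinAlgError("sigma is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.abs(np.diagonal(c)))))
    quad = float(np.real(np.vdot(x, cho_solve((c, low), x))))
    return -(r * np.log(np.pi) + logdet) - quad


def complex_wishart_loglik(
    sample_cs: CrossSpectrum, scale: CrossSpectrum, dof: int
) -> np.ndarray:
    """Unnormalized complex Wishart log-density per frequency.

    Returns ``(M - R) log|S_bar| - M log|S| - M tr(S^{-1} S_bar)`` for each
    frequency, where ``S_bar`` is the sample cross-spectrum and ``S`` the
    scale.  The additive normalization constant, which depends only on
    ``S_bar``, M, and R, is dropped: it never affects estimation in the
    scale matrix.
    """
    r = sample_cs.num_channels
    if dof < r:
        raise ValueError(f"degrees of freedom M={dof} must be >= dimension R={r}")
    if scale.num_channels != r or scale.grid.num_frequencies != sample_cs.grid.num_frequencies:
        raise ValueError("sample and scale cross-spectra must be conformal")
    out = np.empty(sample_cs.grid.num_frequencies)
    for k, (sbar, s) in enumerate(zip(sample_cs.matrices, scale.matrices)):
        sign, logdet_s = np.linalg.slogdet(s)
        if sign.real <= 0:
            raise np.linalg.LinAlgError(f"singular scale at frequency index {k}")
        term = -dof * logdet_s - dof * float(np.real(np.trace(solve(s, sbar))))
        if dof > r:
            sign_b, logdet_b = np.linalg.slogdet(sbar)
            term += (dof - r) * (logdet_b if sign_b.real > 0 else -np.inf)
        out[k] = term
    return out


@dataclass(frozen=True)
class GaussianityResult:
    """Outcome of the per-coefficient Gaussianity test."""

    table: pd.DataFrame
    rejection_fraction: float
    uncorrected_rejection_fraction: float
    num_tests: int
    num_degenerate: int


def gaussianity_test(
    instances: FourierInstances, alpha: float = 0.05
) -> GaussianityResult:
    """Per-coefficient normality test of Fourier coefficients.

    For every (frequency, channel) pair the real and imaginary parts across
    segments are each submitted to a Shapiro-Wilk test; p-values are
    corrected with Benjamini-Hochberg across all channels x frequencies x
    parts at level ``alpha``.  Coefficients that are numerically constant
    are flagged degenerate and excluded.  Under the asymptotic complex
    Gaussian regime the uncorrected per-test rejection fraction is close to
    ``alpha``; the BH-corrected fraction is near zero at the global null.
    """
    m = instances.num_segments
    if m < 20:
        raise ValueError("at least 20 segments are required for the test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for fi, freq in enumerate(instances.grid.frequencies):
        for ch in range(instances.num_channels):
            coeff = instances.values[:, ch, fi]
            for part, series in (("real", coeff.real), ("imag", coeff.imag)):
                degenerate = float(np.ptp(series)) <= 1e-12 * (
                    float(np.abs(series).max()) + 1e-300
                )
                if degenerate:
                    stat, pval = np.nan, np.nan
                else:
                    stat, pval = stats.shapiro(series)
                rows.append(
                    {
                        "frequency": freq,
                        "channel": ch,
                        "part": part,
                        "statistic": stat,
                        "pvalue": pval,
                        "degenerate": degenerate,
                    }
                )
    table = pd.DataFrame(rows)
    tested = ~table["degenerate"]
    reject = np.zeros(len(table), dtype=bool)
    if tested.any():
        reject[tested.to_numpy()] = multipletests(
            table.loc[tested, "pvalue"].to_numpy(), alpha=alpha, method="fdr_bh"
        )[0]
    table["reject"] = reject
    n_tests = int(tested.sum())
    frac = float(reject.sum() / n_tests) if n_tests else float("nan")
    raw_frac = (
        float((table.loc[tested, "pvalue"] < alpha).mean()) if n_tests else float("nan")
    )
    return GaussianityResult(
        table=table,
        rejection_fraction=frac,
        uncorrected_rejection_fraction=raw_frac,
        num_tests=n_tests,
        num_degenerate=int((~tested).sum()),
    )


def band_average(
    cs: CrossSpectrum, bands: dict[str, tuple[float, float]] | None = None
) -> CrossSpectrum:
    """Average per-frequency matrices within named closed-open bands.

    Returns a :class:`CrossSpectrum` with one matrix per band; the grid
    frequencies are the band centers and ``band_names`` records the order.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if not bands:
        raise ValueError("at least one band is required")
    freqs = cs.grid.frequencies
    names, centers, mats = [], [], []
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"band {name!r} [{lo}, {hi}) contains no grid frequency")
        names.append(name)
        centers.append(0.5 * (lo + hi))
        mats.append(cs.matrices[mask].mean(axis=0))
    order = np.argsort(centers)
    grid = replace(
        cs.grid, frequencies=np.asarray([centers[i] for i in order], dtype=float)
    )
    return CrossSpectrum(
        np.stack([mats[i] for i in order]),
        cs.sample_size,
        grid,
        space_tag=cs.space_tag,
        band_names=tuple(names[i] for i in order),
    )
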