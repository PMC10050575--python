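"""Quasilinear inverse operators for cross-spectral source imaging.

All solvers return operators ``T`` (sources x sensors, real) that are
applied linearly to data cross-spectra, ``Sigma_hat_ii = T Sigma_vv T^T``.
The family covers the classical MAP baselines

* sMNE      -- minimum-norm estimate, ``Pi = (L^T B^-1 L + alpha A^-1)^-1``,
               ``T = Pi L^T B^-1``;
* seLORETA  -- the same operator with a diagonal source weight obtained from
               the eLORETA fixed point, which yields zero peak-localization
               error for a single point source;
* sLCMV     -- per-source unit-gain minimum-variance beamformer rows;

and the package's main solver

* ssSBL     -- spectral structured sparse Bayesian learning: per frequency,
               an evidence-maximization (gamma-MAP) EM loop over per-source
               variances ``gamma`` with an Elastic-Net hyper-penalty
               ``a1 * sum sqrt(gamma) + a2 * sum gamma`` that induces a
               sparse-plus-smooth source spectrum.  The E-step is the
               Gaussian posterior of the iterated quasilinear operator; the
               M-step maximizes, per source, the surrogate

                   Q(g) = -M log g - M m2 / g - a1 sqrt(g) - a2 g

               where ``m2`` is the posterior second moment.  At
               ``a1 = a2 = 0`` this reduces to the classic SBL fixed point
               ``gamma <- m2``.

Lead field and data are rescaled before solving so that
``trace(L L^T) / E = 1`` and ``trace(Sigma_vv) / E = 1``; penalties are
therefore dimensionless.  Results are reported back on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve

from cesi.forward import LeadField
from cesi.spectral import CrossSpectrum

__all__ = [
    "QuasilinearOperator",
    "SsSBLState",
    "SolverConfig",
    "smne_operator",
    "seloreta_operator",
    "slcmv_operator",
    "sssbl_solve",
    "apply_operator",
    "cst_from_cross_spectrum",
]


def _lf_matrix(L) -> np.ndarray:
    return L.matrix if isinstance(L, LeadField) else np.asarray(L, dtype=float)


@dataclass
class QuasilinearOperator:
    """Inverse operator T (G x E) with posterior covariance and metadata."""

    T: np.ndarray
    Pi: np.ndarray | None
    method: str
    hyperparameters: dict = field(default_factory=dict)
    frequency: float | str | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 2:
            raise ValueError("T must be a 2-D matrix")
        if self.Pi is not None:
            self.Pi = np.asarray(self.Pi, dtype=float)

    @property
    def num_sources(self) -> int:
        return int(self.T.shape[0])

    @property
    def num_sensors(self) -> int:
        return int(self.T.shape[1])


@dataclass
class SsSBLState:
    """Per-frequency state of the ssSBL gamma-MAP loop.

    ``gamma`` (F, G) and ``beta`` (F, E) are the converged variational and
    noise spectra (source-power / sensor-power units on the original data
    scale); ``objective_trace`` holds, per frequency, the penalized evidence
    surrogate per iteration (non-decreasing up to numerical tolerance).
    """

    gamma: np.ndarray
    beta: np.ndarray
    iterations: list[int]
    objective_trace: list[np.ndarray]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.gamma < 0) or np.any(self.beta < 0):
            raise ValueError("gamma and beta must be elementwise nonnegative")


@dataclass
class SolverConfig:
    """Hyperparameters shared by the solver family.

    ``alpha`` is the MAP1 regularization temperature (sMNE / seLORETA);
    ``alpha1`` and ``alpha2`` weight the sparse (square-root) and smooth
    (trace) terms of the ssSBL Elastic-Net hyper-penalty.  All three are
    dimensionless thanks to the data-driven rescaling.
    """

    alpha: float = 1e-2
    alpha1: float = 1.0
    alpha2: float = 1e-2
    max_iter: int = 200
    tol: float = 1e-6
    seed: int | None = None
    noise_update: bool = False
    beta0: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not np.isfinite([self.alpha, self.alpha1, self.alpha2, self.tol]).all():
            raise ValueError("scalar hyperparameters must be finite")


def _psd_pinv(mat: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Pseudo-inverse of a symmetric PSD matrix via eigendecomposition."""
    w, v = np.linalg.eigh(0.5 * (mat + mat.T))
    cutoff = rcond * max(w.max(), 0.0)
    inv_w = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
    return (v * inv_w) @ v.T


def smne_operator(
    L, B: np.ndarray | None = None, alpha: float = 1e-2, A: np.ndarray | None = None
) -> QuasilinearOperator:
    """Spectral minimum-norm operator.

    ``Pi = (L^T B^-1 L + alpha A^-1)^-1`` and ``T = Pi L^T B^-1``; for
    ``G > E`` this is evaluated in the numerically cheaper dual form
    ``T = A L^T (L A L^T + alpha B)^-1``.  ``A`` defaults to the identity
    (plain MNE) and ``B`` to the identity sensor covariance.
    """
    lf = _lf_matrix(L)
    e, g = lf.shape
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    B = np.eye(e) if B is None else np.asarray(B, dtype=float)
    sign, _ = np.linalg.slogdet(B)
    if sign <= 0:
        raise np.linalg.LinAlgError("sensor matrix B must be positive definite")
    if g > e:
        Amat = np.eye(g) if A is None else np.asarray(A, dtype=float)
        LA = lf @ Amat
        M = LA @ lf.T + alpha * B
        T = Amat @ lf.T @ np.linalg.inv(M)
        # Woodbury: (L^T B^-1 L + alpha A^-1)^-1 = (A - A L^T M^-1 L A)/alpha
        Pi = (Amat - T @ LA) / alpha
    else:
        Amat = np.eye(g) if A is None else np.asarray(A, dtype=float)
        Pi = np.linalg.inv(lf.T @ solve(B, lf) + alpha * np.linalg.inv(Amat))
        T = Pi @ lf.T @ np.linalg.inv(B)
    Pi = 0.5 * (Pi + Pi.T)
    return QuasilinearOperator(
        T, Pi, "smne", {"alpha": float(alpha), "A": "identity" if A is None else "given", "B": "identity" if B is None else "given"},
    )


def seloreta_operator(
    L,
    B: np.ndarray | None = None,
    alpha: float = 1e-2,
    max_iter: int = 2000,
    tol: float = 1e-8,
    damping: float = 0.5,
) -> QuasilinearOperator:
    """Spectral eLORETA operator.

    Iterates the eLORETA weight fixed point
    ``w_g = sqrt(l_g^T (L diag(w)^-1 L^T + alpha B)^+ l_g)`` with damped
    updates, then returns the constrained generalized inverse with source
    weight matrix ``A = diag(w)^-1``.  The resulting operator has zero
    peak-localization error for a single noiseless point source.
    """
    lf = _lf_matrix(L)
    e, g = lf.shape
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    B = np.eye(e) if B is None else np.asarray(B, dtype=float)
    w = np.ones(g)
    residual = np.inf
    for _ in range(max_iter):
        M = _psd_pinv((lf / w) @ lf.T + alpha * B)
        w_new = np.sqrt(np.maximum(np.einsum("eg,ef,fg->g", lf, M, lf), 0.0))
        w_new = np.maximum(w_new, 1e-300)
        residual = float(np.max(np.abs(w - w_new) / np.maximum(w_new, 1e-300)))
        w = damping * w + (1.0 - damping) * w_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"eLORETA weights did not converge in {max_iter} iterations "
            f"(last relative residual {residual:.3e})"
        )
    M = _psd_pinv((lf / w) @ lf.T + alpha * B)
    T = (lf / w).T @ M
    Pi = (np.diag(1.0 / w) - T @ (lf / w)) / alpha
    Pi = 0.5 * (Pi + Pi.T)
    return QuasilinearOperator(
        T, Pi, "seloreta",
        {"alpha": float(alpha), "A": "eloreta-diag", "B": "identity" if B is None else "given", "residual": residual},
    )


def slcmv_operator(
    L, data_cs: CrossSpectrum, regularization: float | None = None
) -> list[QuasilinearOperator]:
    """Spectral LCMV beamformer, one operator per frequency.

    Row ``g`` of ``T`` is the unit-gain minimum-variance filter
    ``w_g^T = (l_g^T C^-1 l_g)^-1 l_g^T C^-1`` with
    ``C = Re(Sigma_vv) + regularization I`` (diagonal loading; the real part
    keeps the operator real so that the estimated source cross-spectrum is
    automatically Hermitian).  Default loading is
    ``1e-3 trace(Sigma_vv) / E``.
    """
    lf = _lf_matrix(L)
    e = lf.shape[0]
    if data_cs.num_channels != e:
        raise ValueError("data cross-spectrum does not match the lead field")
    ops = []
    for k, mat in enumerate(data_cs.matrices):
        C = np.real(mat).astype(float)
        load = (
            1e-3 * np.trace(C) / e if regularization is None else float(regularization)
        )
        C = C + load * np.eye(e)
        try:
            Cinv_L = solve(C, lf, assume_a="pos")
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular beamformer covariance at frequency index {k}; "
                "increase the diagonal loading"
            ) from exc
        gains = np.einsum("eg,eg->g", lf, Cinv_L)
        if np.any(gains <= 0):
            raise np.linalg.LinAlgError(
                f"non-positive beamformer gain at frequency index {k}"
            )
        T = (Cinv_L / gains).T
        tag = (
            data_cs.band_names[k]
            if data_cs.band_names is not None
            else float(data_cs.grid.frequencies[k])
        )
        ops.append(
            QuasilinearOperator(
                T, None, "slcmv", {"regularization": float(load)}, frequency=tag
            )
        )
    return ops


def _gamma_step(m2: np.ndarray, M: int, a1: float, a2: float) -> np.ndarray:
    """Per-source maximizer of Q(g) = -M log g - M m2/g - a1 sqrt(g) - a2 g.

    The stationarity condition multiplied by g^2 gives
    ``h(g) = M m2 - M g - (a1/2) g^{3/2} - a2 g^2 = 0`` with ``h`` strictly
    decreasing and ``h(0) = M m2 >= 0``, so the root is unique and lies in
    ``[0, m2]``; it is found by vectorized bisection.
    """
    m2 = np.maximum(m2, 0.0)
    lo = np.zeros_like(m2)
    hi = m2.copy()
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        h = M * m2 - M * mid - 0.5 * a1 * mid**1.5 - a2 * mid**2
        take = h > 0
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    return 0.5 * (lo + hi)


def _sssbl_objective(
    lf: np.ndarray, gamma: np.ndarray, beta: np.ndarray, sigma: np.ndarray,
    M: int, a1: float, a2: float,
) -> float:
    """Penalized evidence surrogate (up to an additive constant)."""
    cov = (lf * gamma) @ lf.T + np.diag(beta)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    fit = float(np.real(np.trace(solve(cov, sigma))))
    return (
        -M * logdet - M * fit - a1 * float(np.sum(np.sqrt(gamma))) - a2 * float(np.sum(gamma))
    )


def _default_beta(sigma_real: np.ndarray) -> float:
    """Noise-floor estimate: mean of the smallest quartile of eigenvalues."""
    w = np.linalg.eigvalsh(sigma_real)
    k = max(1, w.size // 4)
    return float(np.maximum(w[:k].mean(), 1e-12 * w[-1]))


def sssbl_solve(
    data_cs: CrossSpectrum, L, config: SolverConfig | None = None
) -> tuple[list[QuasilinearOperator], SsSBLState, CrossSpectrum]:
    """Spectral structured sparse Bayesian learning (gamma-MAP) solver.

    Runs the EM loop independently per frequency (pass a band-averaged
    cross-spectrum for band pooling).  Returns the per-frequency operators,
    the solver state (with non-decreasing objective traces), and the
    estimated source cross-spectrum ``T Sigma_vv T^T``.
    """
    cfg = config or SolverConfig()
    lf0 = _lf_matrix(L)
    e, g = lf0.shape
    if data_cs.num_channels != e:
        raise ValueError("data cross-spectrum does not match the lead field")
    M = int(data_cs.sample_size)
    if M < 1:
        raise ValueError("data cross-spectrum must record a sample size >= 1")

    # data-driven rescaling: trace(L L^T)/E = 1 and trace(Sigma)/E = 1
    c = float(np.sqrt(np.trace(lf0 @ lf0.T) / e))
    lf = lf0 / c

    nf = data_cs.grid.num_frequencies
    gammas = np.zeros((nf, g))
    betas = np.zeros((nf, e))
    ops: list[QuasilinearOperator] = []
    src_mats = np.zeros((nf, g, g), dtype=complex)
    traces: list[np.ndarray] = []
    iters: list[int] = []

    for k in range(nf):
        mat0 = data_cs.matrices[k]
        s = float(np.real(np.trace(mat0)) / e)
        if s <= 0:
            raise ValueError(f"zero-power data matrix at frequency index {k}")
        sigma = mat0 / s
        sigma_r = np.real(sigma)

        if cfg.beta0 is None:
            beta = np.full(e, _default_beta(sigma_r))
        else:
            beta = (np.ones(e) * np.asarray(cfg.beta0, dtype=float) / s).ravel()
            if beta.size != e:
                raise ValueError("beta0 must be scalar or length-E")
        beta = np.maximum(beta, 1e-12)
        gamma = np.full(g, e / g)  # uniform, trace-matched to scaled data

        trace_vals = [
            _sssbl_objective(lf, gamma, beta, sigma, M, cfg.alpha1, cfg.alpha2)
        ]
        n_it = 0
        for n_it in range(1, cfg.max_iter + 1):
            # E-step via the dual (Woodbury) form: all inversions are E x E
            LG = lf * gamma  # (E, G) columns scaled
            Minv = np.linalg.inv(LG @ lf.T + np.diag(beta))
            T = LG.T @ Minv  # (G, E)
            # diag of Pi = Gamma - Gamma L^T Minv L Gamma
            pi_diag = np.maximum(gamma - np.einsum("ge,eg->g", T, LG), 0.0)
            m2 = np.real(np.einsum("ge,ef,gf->g", T, sigma, T)) + pi_diag
            gamma_new = _gamma_step(m2, M, cfg.alpha1, cfg.alpha2)
            delta = float(
                np.max(np.abs(gamma_new - gamma)) / (np.max(gamma) + 1e-300)
            )
            gamma = gamma_new
            if cfg.noise_update:
                TS = T @ sigma
                resid = (
                    sigma_r
                    - np.real(lf @ TS)
                    - np.real(lf @ TS).T
                    + lf @ (np.real(TS @ T.T) + np.diag(pi_diag)) @ lf.T
                )
                beta = np.maximum(np.diag(resid), 1e-12)
            obj = _sssbl_objective(lf, gamma, beta, sigma, M, cfg.alpha1, cfg.alpha2)
            if not np.isfinite(obj):
                raise FloatingPointError(
                    f"non-finite ssSBL objective at frequency index {k}"
                )
            trace_vals.append(obj)
            if delta < cfg.tol:
                break

        # final operator at the converged gamma
        LG = lf * gamma
        Minv = np.linalg.inv(LG @ lf.T + np.diag(beta))
        T = LG.T @ Minv
        pi_diag = np.maximum(gamma - np.einsum("ge,eg->g", T, LG), 0.0)

        # undo the rescaling: T maps original sensor data to original sources
        T_out = T * (1.0 / c)
        tag = (
            data_cs.band_names[k]
            if data_cs.band_names is not None
            else float(data_cs.grid.frequencies[k])
        )
        ops.append(
            QuasilinearOperator(
                T_out,
                pi_diag * s / c**2,
                "sssbl",
                {
                    "alpha1": cfg.alpha1,
                    "alpha2": cfg.alpha2,
                    "data_scale": s,
                    "leadfield_scale": c,
                },
                frequency=tag,
            )
        )
        gammas[k] = gamma * s / c**2
        betas[k] = beta * s
        est = T_out @ mat0 @ T_out.T
        src_mats[k] = 0.5 * (est + est.conj().T)
        traces.append(np.asarray(trace_vals))
        iters.append(n_it)

    state = SsSBLState(gammas, betas, iters, traces)
    src_cs = CrossSpectrum(
        src_mats, M, data_cs.grid, space_tag="source", band_names=data_cs.band_names
    )
    return ops, state, src_cs


def apply_operator(
    op: QuasilinearOperator | list[QuasilinearOperator], data_cs: CrossSpectrum
) -> CrossSpectrum:
    """Map a sensor cross-spectrum to source space: T Sigma_vv T^T.

    Accepts a single operator (applied at every frequency) or one operator
    per frequency.
    """
    if isinstance(op, QuasilinearOperator):
        ops = [op] * data_cs.grid.num_frequencies
    else:
        ops = list(op)
        if len(ops) != data_cs.grid.num_frequencies:
            raise ValueError("need one operator per frequency")
    if any(o.num_sensors != data_cs.num_channels for o in ops):
        raise ValueError("operator and cross-spectrum dimensions disagree")
    mats = np.stack([o.T @ m @ o.T.T for o, m in zip(ops, data_cs.matrices)])
    mats = 0.5 * (mats + np.conj(np.transpose(mats, (0, 2, 1))))
    return CrossSpectrum(
        mats,
        data_cs.sample_size,
        data_cs.grid,
        space_tag="source",
        band_names=data_cs.band_names,
    )


def cst_from_cross_spectrum(src_cs: CrossSpectrum) -> np.ndarray:
    """Cortical spectral topography: the real diagonal per frequency, (F, G)."""
    return src_cs.diagonal()
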