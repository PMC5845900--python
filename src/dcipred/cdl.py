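"""Masked convolutional dictionary learning for 1-D physiologic series.

The model represents a series ``X`` as a sparse sum of shift-invariant kernels,

    minimize_{D, Gamma}  || W (X - sum_k d_k * Gamma_k) ||_2^2 + lambda * sum_k ||Gamma_k||_1,

where ``d_k`` are unit-norm kernels of common length ``r``, ``Gamma_k`` are
activation maps over the whole series, ``*`` is convolution and ``W`` is a
binary mask that zeroes the residual wherever data is missing (mask
decoupling). Both subproblems — sparse coding with ``D`` fixed, and the
dictionary update with ``Gamma`` fixed — are solved by ADMM. Convolutions are
circular in the frequency domain on a zero-padded support whose padded tail is
masked out, so wrap-around never contributes to the objective.

The multiscale driver learns one dictionary per (variable, downsampling
period, kernel length) cell of a grid; with the default grid of 5 variables,
7 periods {1,5,10,20,60,120,240} min, 6 kernel lengths {2,5,8,10,20,40} and
K=20 kernels each, the bank holds 210 dictionaries / 4,200 atoms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.fft import next_fast_len

from .timeseries import Cohort, TimeSeries, VARIABLES, DS_PERIODS_MIN, \
    censor_window, contiguous_runs, downsample_mean

#: kernel lengths (in samples) of the default multiscale grid
KERNEL_LENGTHS = (2, 5, 8, 10, 20, 40)


@dataclass
class CDLConfig:
    """Solver parameters (the model itself fixes none of these).

    ``lam=None`` selects lambda = 0.1 * max_k max_t |(d_k ⋆ WX)(t)| at
    initialization — a fixed fraction of the smallest lambda that zeroes
    every coefficient. ``rho=None`` starts the ADMM penalty at 10*lambda
    with residual-balancing adaptation.
    """

    lam: Optional[float] = None
    lam_frac: float = 0.1  # lambda as a fraction of lambda_max when lam is None
    max_outer_iters: int = 15
    max_admm_iters: int = 100
    rho: Optional[float] = None
    rel_tol: float = 1e-4
    seed: int = 0
    max_series: int = 50   # series subsampled per dictionary for tractability

    def __post_init__(self) -> None:
        if self.max_outer_iters <= 0 or self.max_admm_iters <= 0:
            raise ValueError("iteration limits must be positive")
        if not (0 < self.rel_tol < 1):
            raise ValueError("rel_tol must lie in (0,1)")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class Dictionary:
    """K kernels of common length, tied to one (variable, ds period) cell."""

    atoms: np.ndarray                 # (K, r)
    variable: str = ""
    ds_minutes: float = 0.0
    lam: float = 0.0
    seed: int = 0
    objective_trace: list = field(default_factory=list)
    reseeded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(norms > 1 + 1e-6):
            raise ValueError("atom norms must not exceed 1")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def kernel_length(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCode:
    """Per-kernel activation maps for one series.

    Maps live on the padded circular support of length ``n_padded``; only the
    first ``n_samples`` positions reconstruct the series (the padded tail is
    masked during coding, so activations there are zero up to solver
    tolerance).
    """

    maps: np.ndarray       # (K, n_padded)
    lam: float
    n_samples: int
    objective: float = np.nan
    converged: bool = True


# ---------------------------------------------------------------------------
# circular-convolution helpers
# ---------------------------------------------------------------------------

def _pad_len(n: int, r: int) -> int:
    return next_fast_len(n + r)


def _dhat(atoms: np.ndarray, npad: int) -> np.ndarray:
    pad = np.zeros((atoms.shape[0], npad))
    pad[:, : atoms.shape[1]] = atoms
    return np.fft.rfft(pad, axis=-1)


def reconstruct(dictionary: Dictionary, code: SparseCode) -> np.ndarray:
    """Sum of kernel/activation circular convolutions, cropped to the series."""
    npad = code.maps.shape[1]
    dh = _dhat(dictionary.atoms, npad)
    gh = np.fft.rfft(code.maps, axis=-1)
    rec = np.fft.irfft(np.sum(dh * gh, axis=0), n=npad)
    return rec[: code.n_samples]


def objective(series: TimeSeries, dictionary: Dictionary,
              code: SparseCode) -> tuple:
    """Exact masked objective ``(total, fidelity, l1)``.

    fidelity = ||W(X - sum_k d_k * Gamma_k)||^2 evaluated only at observed
    samples; total = fidelity + lambda * l1.
    """
    rec = reconstruct(dictionary, code)
    resid = np.where(series.mask, np.nan_to_num(series.values) - rec, 0.0)
    fidelity = float(np.dot(resid, resid))
    l1 = float(np.abs(code.maps).sum())
    return fidelity + code.lam * l1, fidelity, l1


# ---------------------------------------------------------------------------
# batched internal representation
# ---------------------------------------------------------------------------

def _stack(series_set: Sequence[TimeSeries], r: int):
    """Zero-fill series into (S, npad) arrays X, W; W=0 on padding and gaps."""
    lengths = [len(s) for s in series_set]
    npad = _pad_len(max(lengths), r)
    S = len(series_set)
    X = np.zeros((S, npad))
    W = np.zeros((S, npad))
    for i, s in enumerate(series_set):
        X[i, : len(s)] = np.nan_to_num(s.values)
        W[i, : len(s)] = s.mask.astype(float)
    X *= W
    return X, W, lengths, npad


def _lambda_max(atoms: np.ndarray, X: np.ndarray, W: np.ndarray) -> float:
    """max_k max_t |(d_k ⋆ WX)(t)| — correlation of atoms with the masked data."""
    npad = X.shape[1]
    dh = _dhat(atoms, npad)
    xh = np.fft.rfft(X * W, axis=-1)
    corr = np.fft.irfft(np.conj(dh)[None] * xh[:, None, :], n=npad, axis=-1)
    return float(np.abs(corr).max())


def _admm_sparse_code(X, W, dh, lam, cfg: CDLConfig, gamma0=None):
    """ADMM for min_G ||W(X - D G)||^2 + lam ||G||_1 with D fixed.

    Splitting: y0 = X - D G (masked residual block), y1 = G (l1 block).
    The G update solves (D^H D + I) per frequency by Sherman-Morrison.
    Returns (Gamma, n_iters, converged).
    """
    S, npad = X.shape
    K = dh.shape[0]
    rho = cfg.rho if cfg.rho is not None else max(10.0 * lam, 1e-3)
    G = np.zeros((S, K, npad)) if gamma0 is None else gamma0.copy()
    gh = np.fft.rfft(G, axis=-1)
    DG = np.fft.irfft(np.sum(dh[None] * gh, axis=1), n=npad, axis=-1)
    y0 = X - DG
    y1 = G.copy()
    u0 = np.zeros_like(X)
    u1 = np.zeros_like(G)
    denom_cache = None
    converged = False
    it = 0
    for it in range(1, cfg.max_admm_iters + 1):
        # G update
        b0 = X - y0 + u0
        b1 = y1 - u1
        b0h = np.fft.rfft(b0, axis=-1)
        b1h = np.fft.rfft(b1, axis=-1)
        rh = np.conj(dh)[None] * b0h[:, None, :] + b1h
        if denom_cache is None:
            denom_cache = 1.0 + np.sum(np.abs(dh) ** 2, axis=0)  # (F,)
        drh = np.sum(dh[None] * rh, axis=1)                      # (S, F)
        gh = rh - np.conj(dh)[None] * (drh / denom_cache)[:, None, :]
        G = np.fft.irfft(gh, n=npad, axis=-1)
        DG = np.fft.irfft(np.sum(dh[None] * gh, axis=1), n=npad, axis=-1)
        # y0 update: prox of ||W y0||^2 (masked residual)
        v0 = X - DG + u0
        y0_new = rho * v0 / (2.0 * W + rho)
        # y1 update: soft threshold
        v1 = G + u1
        y1_new = np.sign(v1) * np.maximum(np.abs(v1) - lam / rho, 0.0)
        # duals
        u0 += X - DG - y0_new
        u1 += G - y1_new
        # residuals
        r_norm = np.sqrt(np.sum((X - DG - y0_new) ** 2) + np.sum((G - y1_new) ** 2))
        s_norm = rho * np.sqrt(np.sum((y0_new - y0) ** 2) + np.sum((y1_new - y1) ** 2))
        y0, y1 = y0_new, y1_new
        scale = max(np.sqrt(np.sum(X ** 2)), 1e-12)
        if r_norm < cfg.rel_tol * scale and s_norm < cfg.rel_tol * scale:
            converged = True
            break
        if it % 10 == 0:  # residual balancing
            if r_norm > 10 * s_norm:
                rho *= 2.0
                u0 /= 2.0
                u1 /= 2.0
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                u0 *= 2.0
                u1 *= 2.0
    return y1, it, converged


def _batch_objective(X, W, dh, G, lam) -> float:
    gh = np.fft.rfft(G, axis=-1)
    DG = np.fft.irfft(np.sum(dh[None] * gh, axis=1), n=X.shape[1], axis=-1)
    resid = W * (X - DG)
    return float(np.sum(resid ** 2) + lam * np.abs(G).sum())


def sparse_code(series: TimeSeries, dictionary: Dictionary,
                lam: Optional[float] = None,
                config: Optional[CDLConfig] = None) -> SparseCode:
    """Sparse coding of one series against a fixed dictionary (masked lasso).

    Minimizes ``||W(X - sum d_k * Gamma_k)||^2 + lam ||Gamma||_1`` by ADMM
    with mask decoupling; masked samples contribute zero residual. On
    non-convergence the best iterate is returned with ``converged=False``.
    """
    cfg = config or CDLConfig()
    r = dictionary.kernel_length
    runs = contiguous_runs(series)
    if not runs or max(b - a for a, b in runs) < r:
        raise ValueError("kernel length exceeds the observed support")
    X, W, lengths, npad = _stack([series], r)
    dh = _dhat(dictionary.atoms, npad)
    if lam is None:
        lam = dictionary.lam if dictionary.lam > 0 else cfg.lam_frac * _lambda_max(
            dictionary.atoms, X, W)
    G, _, conv = _admm_sparse_code(X, W, dh, lam, cfg)
    code = SparseCode(G[0], lam, lengths[0], converged=conv)
    code.objective = objective(series, dictionary, code)[0]
    if not conv:
        warnings.warn("sparse_code: ADMM hit max_admm_iters; best iterate returned")
    return code


# ---------------------------------------------------------------------------
# dictionary update (masked CCMOD by ADMM)
# ---------------------------------------------------------------------------

def _admm_dict_update(X, W, G, r, d0, cfg: CDLConfig):
    """min_d sum_s ||W_s (X_s - conv(d, G_s))||^2  s.t. support r, ||d_k|| <= 1."""
    S, K, npad = G.shape
    gh = np.fft.rfft(G, axis=-1)                     # (S, K, F)
    F = gh.shape[-1]
    rho = cfg.rho if cfg.rho is not None else 1.0
    # per-frequency normal matrix  A(f) = sum_s g_s(f) g_s(f)^H + I
    A = np.einsum("skf,slf->fkl", np.conj(gh), gh) + np.eye(K)[None]
    d = np.zeros((K, npad))
    d[:, :r] = d0
    dh = np.fft.rfft(d, axis=-1)
    Gd = np.fft.irfft(np.einsum("skf,kf->sf", gh, dh), n=npad, axis=-1)
    y0 = X - Gd
    g_var = d.copy()
    u0 = np.zeros_like(X)
    ug = np.zeros_like(d)
    for it in range(1, cfg.max_admm_iters + 1):
        b0 = X - y0 + u0
        b0h = np.fft.rfft(b0, axis=-1)
        rhs = np.einsum("skf,sf->fk", np.conj(gh), b0h) \
            + np.fft.rfft(g_var - ug, axis=-1).T      # (F, K)
        dh = np.linalg.solve(A, rhs[..., None])[..., 0].T   # (K, F)
        d = np.fft.irfft(dh, n=npad, axis=-1)
        Gd = np.fft.irfft(np.einsum("skf,kf->sf", gh, dh), n=npad, axis=-1)
        v0 = X - Gd + u0
        y0_new = rho * v0 / (2.0 * W + rho)
        # constraint projection: support then unit ball
        gv = d + ug
        gv[:, r:] = 0.0
        norms = np.linalg.norm(gv[:, :r], axis=1, keepdims=True)
        gv[:, :r] /= np.maximum(norms, 1.0)
        u0 += X - Gd - y0_new
        ug += d - gv
        r_norm = np.sqrt(np.sum((X - Gd - y0_new) ** 2) + np.sum((d - gv) ** 2))
        s_norm = rho * np.sqrt(np.sum((y0_new - y0) ** 2) + np.sum((gv - g_var) ** 2))
        y0, g_var = y0_new, gv
        scale = max(np.sqrt(np.sum(X ** 2)), 1e-12)
        if r_norm < cfg.rel_tol * scale and s_norm < cfg.rel_tol * scale:
            break
        if it % 10 == 0:
            if r_norm > 10 * s_norm:
                rho *= 2.0
                u0 /= 2.0
                ug /= 2.0
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                u0 *= 2.0
                ug *= 2.0
    return g_var[:, :r]


def _masked_fidelity(X, W, dh, G) -> float:
    gh = np.fft.rfft(G, axis=-1)
    DG = np.fft.irfft(np.sum(dh[None] * gh, axis=1), n=X.shape[1], axis=-1)
    return float(np.sum((W * (X - DG)) ** 2))


def _reseed_dead_atoms(atoms, X, W, dh, G, rng) -> tuple:
    """Replace atoms with zero total activation by the worst-reconstructed
    observed segment (unit-normalized). Returns (atoms, reseeded indices)."""
    r = atoms.shape[1]
    energy = np.abs(G).sum(axis=(0, 2))
    dead = np.flatnonzero(energy == 0.0)
    if dead.size == 0:
        return atoms, []
    gh = np.fft.rfft(G, axis=-1)
    DG = np.fft.irfft(np.sum(dh[None] * gh, axis=1), n=X.shape[1], axis=-1)
    resid = W * (X - DG)
    sq = resid ** 2
    # sliding-window residual energy, valid windows only
    kernel = np.ones(r)
    window_energy = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, sq)
    atoms = atoms.copy()
    for k in dead:
        s, t = np.unravel_index(np.argmax(window_energy), window_energy.shape)
        seg = resid[s, t:t + r].copy()
        nrm = np.linalg.norm(seg)
        atoms[k] = seg / nrm if nrm > 0 else _unit_random(rng, r)
        window_energy[s, max(0, t - r):t + r] = -1.0  # avoid re-picking
    return atoms, list(map(int, dead))


def _unit_random(rng, r):
    v = rng.standard_normal(r)
    return v / np.linalg.norm(v)


def dictionary_update(series_set: Sequence[TimeSeries],
                      codes: Sequence[SparseCode],
                      dictionary: Dictionary,
                      config: Optional[CDLConfig] = None) -> Dictionary:
    """Update atoms with activations fixed, under ``||d_k||_2 <= 1``.

    The masked least-squares problem is solved by ADMM; the update is accepted
    only if it does not increase the masked fidelity (else the previous atoms
    are kept). Atoms with zero total activation are re-seeded from the
    worst-reconstructed data segment and flagged in ``reseeded``.
    """
    cfg = config or CDLConfig()
    r = dictionary.kernel_length
    X, W, lengths, npad = _stack(series_set, r)
    G = np.stack([c.maps for c in codes])
    if G.shape[2] != npad:
        raise ValueError("codes were not computed on this series set")
    dh_old = _dhat(dictionary.atoms, npad)
    fid_before = _masked_fidelity(X, W, dh_old, G)
    new_atoms = _admm_dict_update(X, W, G, r, dictionary.atoms, cfg)
    fid_after = _masked_fidelity(X, W, _dhat(new_atoms, npad), G)
    if fid_after > fid_before:   # ADMM is not monotone; keep the better point
        new_atoms = dictionary.atoms.copy()
    rng = np.random.default_rng(dictionary.seed + 104729)
    new_atoms, reseeded = _reseed_dead_atoms(
        new_atoms, X, W, _dhat(new_atoms, npad), G, rng)
    return Dictionary(new_atoms, dictionary.variable, dictionary.ds_minutes,
                      lam=dictionary.lam, seed=dictionary.seed,
                      objective_trace=list(dictionary.objective_trace),
                      reseeded=reseeded)


# ---------------------------------------------------------------------------
# full learning loop
# ---------------------------------------------------------------------------

def learn_dictionary(series_set: Sequence[TimeSeries], K: int = 20,
                     kernel_length: int = 10,
                     lam: Optional[float] = None,
                     config: Optional[CDLConfig] = None) -> Dictionary:
    """Learn K unit-norm kernels by alternating sparse coding and dictionary
    updates from a seeded random initialization.

    Stops when the relative objective change falls below ``config.rel_tol``
    or after ``max_outer_iters`` alternations. Atoms are returned sorted by
    descending total activation energy (ties by first-activation index) so
    repeated runs are bit-for-bit reproducible.
    """
    cfg = config or CDLConfig()
    r = int(kernel_length)
    eligible = [s for s in series_set
                if any(b - a >= 2 * r for a, b in contiguous_runs(s))]
    if not eligible:
        raise ValueError(
            f"no series has a contiguous observed run >= {2 * r} samples")
    rng = np.random.default_rng(cfg.seed)
    if len(eligible) > cfg.max_series:
        idx = rng.choice(len(eligible), size=cfg.max_series, replace=False)
        eligible = [eligible[i] for i in sorted(idx)]
    X, W, lengths, npad = _stack(eligible, r)
    atoms = np.stack([_unit_random(rng, r) for _ in range(K)])
    if lam is None:
        lam = cfg.lam if cfg.lam is not None else cfg.lam_frac * _lambda_max(atoms, X, W)
    trace = []
    G = None
    for outer in range(cfg.max_outer_iters):
        dh = _dhat(atoms, npad)
        G_new, _, _ = _admm_sparse_code(X, W, dh, lam, cfg, gamma0=G)
        if G is not None and _batch_objective(X, W, dh, G, lam) < \
                _batch_objective(X, W, dh, G_new, lam):
            G_new = G           # keep the better iterate (monotone guarantee)
        G = G_new
        obj = _batch_objective(X, W, dh, G, lam)
        trace.append(obj)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= cfg.rel_tol * abs(trace[-2]):
            break
        fid_before = _masked_fidelity(X, W, dh, G)
        new_atoms = _admm_dict_update(X, W, G, r, atoms, cfg)
        if _masked_fidelity(X, W, _dhat(new_atoms, npad), G) <= fid_before:
            atoms = new_atoms
        atoms, _ = _reseed_dead_atoms(atoms, X, W, _dhat(atoms, npad), G, rng)
    # enforce exact unit norm at convergence; rescale activations so the
    # reconstruction (and hence the fidelity) is unchanged and the l1 term
    # can only shrink (atom norms are <= 1 going in)
    norms = np.linalg.norm(atoms, axis=1)
    safe = np.maximum(norms, 1e-12)
    atoms = atoms / safe[:, None]
    G = G * safe[None, :, None]
    # deterministic ordering: activation energy desc, first activation asc
    energy = (G ** 2).sum(axis=(0, 2))
    first = np.array([
        np.flatnonzero(np.abs(G[:, k, :]).max(axis=0) > 0)[0]
        if np.abs(G[:, k, :]).max() > 0 else npad for k in range(K)])
    order = np.lexsort((first, -energy))
    return Dictionary(atoms[order], lam=lam, seed=cfg.seed,
                      objective_trace=trace)


# ---------------------------------------------------------------------------
# patch-based baseline formulation
# ---------------------------------------------------------------------------

def patch_dictionary_learn(patches: np.ndarray, K: int,
                           lam: float = 0.1,
                           config: Optional[CDLConfig] = None) -> tuple:
    """Classical (non-convolutional) dictionary learning on fixed-size patches.

    Alternates lasso sparse coding with a block-coordinate dictionary update
    under ``||d_k|| <= 1``; the objective
    ``sum_i ||x_i - D g_i||^2 + lam * sum_i ||g_i||_1`` is non-increasing.
    Kept as the baseline the convolutional model improves on (a patch
    dictionary accumulates shifted copies of the same motif).
    """
    from sklearn.linear_model import Lasso

    cfg = config or CDLConfig()
    P = np.atleast_2d(np.asarray(patches, dtype=float))
    N, r = P.shape
    if N < K:
        raise ValueError("need at least K patches")
    if r < 2:
        raise ValueError("patch length must be >= 2")
    if not np.any(P):
        raise ValueError("degenerate input: all patches are zero")
    rng = np.random.default_rng(cfg.seed)
    D = np.stack([_unit_random(rng, r) for _ in range(K)]).T  # (r, K)
    # sklearn's multi-target lasso fits each patch independently, which is
    # exactly the per-patch sparse-coding step; alpha maps our lam onto its
    # (1/(2 n_samples)) ||.||^2 + alpha ||.||_1 convention with n_samples = r
    lasso = Lasso(alpha=lam / (2.0 * r), fit_intercept=False,
                  max_iter=5000, tol=1e-10)
    trace = []
    Gm = np.zeros((K, N))
    for outer in range(cfg.max_outer_iters):
        lasso.fit(D, P.T)
        Gm = np.atleast_2d(lasso.coef_).reshape(N, K).T
        obj = float(np.sum((P.T - D @ Gm) ** 2) + lam * np.abs(Gm).sum())
        trace.append(obj)
        if len(trace) >= 3 and abs(trace[-2] - trace[-1]) <= cfg.rel_tol * abs(trace[-2]):
            break
        # block-coordinate dictionary update with ball projection (exact per atom)
        R = P.T - D @ Gm
        for k in range(K):
            gk = Gm[k]
            nk = float(gk @ gk)
            if nk == 0:
                continue
            Rk = R + np.outer(D[:, k], gk)
            dk = Rk @ gk / nk
            nrm = np.linalg.norm(dk)
            if nrm > 1.0:
                dk = dk / nrm
            R = Rk - np.outer(dk, gk)
            D[:, k] = dk
    # unit-normalize and rescale coefficients so D @ Gm (and the fidelity)
    # is unchanged while the l1 term can only shrink
    norms = np.maximum(np.linalg.norm(D, axis=0), 1e-12)
    D = D / norms[None, :]
    Gm = Gm * norms[:, None]
    trace.append(float(np.sum((P.T - D @ Gm) ** 2) + lam * np.abs(Gm).sum()))
    dictionary = Dictionary(D.T, lam=lam, seed=cfg.seed, objective_trace=trace)
    return dictionary, Gm.T  # sparse vectors, one row per patch


# ---------------------------------------------------------------------------
# multiscale bank
# ---------------------------------------------------------------------------

@dataclass
class DictionaryBank:
    """One dictionary per (variable, ds-period, kernel-length) grid cell.

    ``entries`` maps the triple to a :class:`Dictionary` or ``None`` when no
    patient had a contiguous observed run of at least twice the kernel
    length at that scale. ``norm_stats`` holds the per-variable mean/SD used
    to z-score series before learning (and again at featurization).
    """

    entries: dict = field(default_factory=dict)
    norm_stats: dict = field(default_factory=dict)   # var -> (mean, sd)
    seed: int = 0

    @property
    def n_dictionaries(self) -> int:
        return sum(1 for d in self.entries.values() if d is not None)

    @property
    def n_empty(self) -> int:
        return sum(1 for d in self.entries.values() if d is None)

    @property
    def n_atoms(self) -> int:
        return sum(d.n_atoms for d in self.entries.values() if d is not None)

    def iter_atoms(self):
        """Yield (variable, ds_minutes, kernel_length, kernel_index, atom)."""
        for (var, ds, kl), dct in sorted(self.entries.items(),
                                         key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
            if dct is None:
                continue
            for k in range(dct.n_atoms):
                yield var, ds, kl, k, dct.atoms[k]

    def save(self, path) -> None:
        """Single JSON file; floats serialize via repr so reload is bit-exact."""
        payload = {
            "seed": self.seed,
            "norm_stats": {v: list(map(float, st)) for v, st in self.norm_stats.items()},
            "entries": [
                {
                    "variable": var, "ds_minutes": ds, "kernel_length": kl,
                    "empty": dct is None,
                    "atoms": None if dct is None else dct.atoms.tolist(),
                    "lam": None if dct is None else dct.lam,
                    "dict_seed": None if dct is None else dct.seed,
                    "objective_trace": None if dct is None else list(dct.objective_trace),
                }
                for (var, ds, kl), dct in sorted(self.entries.items())
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DictionaryBank":
        payload = json.loads(Path(path).read_text())
        bank = cls(seed=payload["seed"],
                   norm_stats={v: tuple(st) for v, st in payload["norm_stats"].items()})
        for e in payload["entries"]:
            key = (e["variable"], e["ds_minutes"], e["kernel_length"])
            if e["empty"]:
                bank.entries[key] = None
            else:
                bank.entries[key] = Dictionary(
                    np.array(e["atoms"]), e["variable"], e["ds_minutes"],
                    lam=e["lam"], seed=e["dict_seed"],
                    objective_trace=e["objective_trace"])
        return bank


def zscore_stats(cohort: Cohort, variables=VARIABLES,
                 censor_days: Optional[float] = 4.0) -> dict:
    """Per-variable mean/SD over all observed samples of all patients."""
    stats = {}
    for var in variables:
        chunks = []
        for rec in cohort:
            ts = rec.channels.get(var)
            if ts is None:
                continue
            if censor_days is not None:
                ts = censor_window(ts, censor_days)
            chunks.append(ts.observed_values())
        pooled = np.concatenate(chunks) if chunks else np.empty(0)
        if pooled.size >= 2:
            sd = float(pooled.std())
            stats[var] = (float(pooled.mean()), sd if sd > 0 else 1.0)
        else:
            stats[var] = (0.0, 1.0)
    return stats


def prepare_series(rec_channels: dict, var: str, ds_minutes: float,
                   stats: dict, censor_days: Optional[float] = 4.0):
    """Censor -> downsample-by-mean -> z-score one channel; None if absent."""
    ts = rec_channels.get(var)
    if ts is None:
        return None
    if censor_days is not None:
        ts = censor_window(ts, censor_days)
    if len(ts) == 0:
        return None
    ts = downsample_mean(ts, ds_minutes)
    mean, sd = stats.get(var, (0.0, 1.0))
    vals = (ts.values - mean) / sd
    return TimeSeries(vals, ts.period, ts.start, ts.mask)


def learn_multiscale(cohort: Cohort, variables=VARIABLES,
                     ds_periods=DS_PERIODS_MIN,
                     kernel_lengths=KERNEL_LENGTHS, K: int = 20,
                     config: Optional[CDLConfig] = None,
                     censor_days: Optional[float] = 4.0) -> DictionaryBank:
    """Learn the full multiscale dictionary bank.

    For every (variable, downsampling period, kernel length) cell, the
    censored, downsampled, z-scored series of all patients are pooled and a
    K-kernel dictionary is learned. Cells where no patient has a contiguous
    observed run of at least 2x the kernel length are recorded as empty with
    a warning.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    cfg = config or CDLConfig()
    stats = zscore_stats(cohort, variables, censor_days)
    bank = DictionaryBank(norm_stats=stats, seed=cfg.seed)
    for vi, var in enumerate(variables):
        for di, ds in enumerate(ds_periods):
            pool = []
            for rec in cohort:
                s = prepare_series(rec.channels, var, ds, stats, censor_days)
                if s is not None and s.n_observed > 0:
                    pool.append(s)
            for ki, kl in enumerate(kernel_lengths):
                eligible = [s for s in pool
                            if any(b - a >= 2 * kl for a, b in contiguous_runs(s))]
                key = (var, float(ds), int(kl))
                if not eligible:
                    warnings.warn(
                        f"no contiguous run >= {2 * kl} samples for "
                        f"{var} at ds={ds} min, KL={kl}: dictionary left empty")
                    bank.entries[key] = None
                    continue
                # decorrelated per-cell seed, deterministic in (cfg.seed, cell)
                cell_seed = (cfg.seed * 1000003 + vi * 10007 + di * 101 + ki) % (2 ** 31)
                cell_cfg = CDLConfig(
                    lam=cfg.lam, lam_frac=cfg.lam_frac,
                    max_outer_iters=cfg.max_outer_iters,
                    max_admm_iters=cfg.max_admm_iters, rho=cfg.rho,
                    rel_tol=cfg.rel_tol, seed=cell_seed,
                    max_series=cfg.max_series)
                dct = learn_dictionary(eligible, K=K, kernel_length=kl,
                                       config=cell_cfg)
                dct.variable = var
                dct.ds_minutes = float(ds)
                bank.entries[key] = dct
    return bank
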