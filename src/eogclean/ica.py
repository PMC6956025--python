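"""Infomax independent component analysis.

Implements the natural-gradient Infomax algorithm with a logistic
nonlinearity: the observed channels ``x`` are modelled as a square linear
mixture ``x = A s`` of statistically independent, non-Gaussian sources, and
the unmixing matrix ``W`` is found by maximizing the entropy of
``phi(W x)`` with ``phi(u) = 1 / (1 + exp(-u))`` via stochastic natural
gradient ascent over mini-batches, with learning-rate annealing when the
update direction oscillates.

Conventions (fixed so downstream peak detection and tests are reproducible):

* data are centered and whitened by PCA before unmixing; average-referenced
  data are rank-deficient by exactly one dimension, which is dropped and
  embedded back through the mixing matrix;
* recovered sources have unit variance;
* the sign of each component is chosen so its largest-magnitude mixing
  weight is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = ["ICADecomposition", "center_whiten", "fit_infomax", "sources", "reconstruct"]

_RANK_TOL = 1e-10


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ICADecomposition:
    """Result of an ICA fit.

    ``W`` is the full unmixing transform (components x channels, applied to
    centered data) and ``A`` its pseudo-inverse mixing matrix (channels x
    components), so ``W @ A`` is the identity and ``A @ S + mean`` reproduces
    the input up to the dropped rank-deficient dimension (exactly, for
    average-referenced input).
    """

    A: np.ndarray
    W: np.ndarray
    S: np.ndarray
    mean: np.ndarray
    whitener: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    fs: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]


def _as_matrix(x) -> tuple[np.ndarray, float | None, list[str] | None]:
    if isinstance(x, Recording):
        return x.data, x.fs, x.labels
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a channels x samples matrix")
    return arr, None, None


def _is_average_referenced(data: np.ndarray, rtol: float = 1e-8) -> bool:
    scale = np.abs(data).max()
    if scale == 0:
        return True
    return np.abs(data.mean(axis=0)).max() <= rtol * scale


def center_whiten(x) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and sphere a channels x samples matrix.

    Returns ``(z, whitener, mean)`` with ``z = whitener @ (x - mean)`` having
    identity sample covariance.  Average-referenced input is rank-deficient
    by one; that single dimension is dropped.  Any further rank deficiency
    (zero-variance channels, duplicated channels) raises an error advising an
    explicit PCA dimension reduction.
    """
    data, _, _ = _as_matrix(x)
    n_ch, n_s = data.shape
    if n_s <= n_ch:
        raise ValueError(f"need more samples ({n_s}) than channels ({n_ch})")
    mean = data.mean(axis=1)
    xc = data - mean[:, None]
    variances = (xc ** 2).mean(axis=1)
    if np.any(variances == 0):
        dead = [i for i, v in enumerate(variances) if v == 0]
        raise ValueError(f"channel(s) {dead} have zero variance; cannot whiten")
    cov = xc @ xc.T / (n_s - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > _RANK_TOL * evals[0]))
    allowed = 1 if _is_average_referenced(data) else 0
    if n_ch - rank > allowed:
        raise ValueError(
            f"covariance rank {rank} < {n_ch - allowed} (beyond the expected "
            "average-reference deficiency); reduce dimensionality with PCA first"
        )
    k = min(rank, n_ch - allowed) if allowed else rank
    whitener = (evecs[:, :k] / np.sqrt(evals[:k])).T
    z = whitener @ xc
    return z, whitener, mean


def _infomax_core(z: np.ndarray, rng: np.random.Generator, max_iter: int,
                  tol: float, lrate: float,
                  lrate_max: float = 0.03) -> tuple[np.ndarray, bool, int]:
    """Natural-gradient Infomax on whitened data ``z`` (k x n).

    The learning rate adapts per sweep: it grows by 5 % while successive
    weight updates stay aligned (angle < 60 degrees) and is cut to 70 % when
    they oscillate, so the iteration takes large steps through the smooth
    early phase and settles once it reaches the stochastic noise ball, where
    the shrinking rate lets the weight change fall below ``tol``.
    Returns ``(W, converged, iterations)``.
    """
    k, n = z.shape
    block = int(min(n, int(np.ceil(np.sqrt(n))) * 8))
    W = np.eye(k)
    eye = np.eye(k)
    old_delta = None
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        W_old = W.copy()
        perm = rng.permutation(n)
        blowup = False
        for start in range(0, n, block):
            zb = z[:, perm[start:start + block]]
            b = zb.shape[1]
            u = W @ zb
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + (lrate / b) * ((eye * b + (1.0 - 2.0 * y) @ u.T) @ W)
            if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                blowup = True
                break
        if blowup:
            lrate *= 0.5
            W = W_old
            old_delta = None
            if lrate < 1e-12:
                raise FloatingPointError(
                    f"Infomax produced non-finite weights at iteration {it}; "
                    "learning rate annealed to zero without recovery"
                )
            continue
        delta = W - W_old
        wchange = float(np.sqrt(np.sum(delta ** 2)))
        if old_delta is not None:
            denom = np.sqrt(np.sum(delta ** 2) * np.sum(old_delta ** 2))
            cosang = float(np.sum(delta * old_delta)) / denom if denom > 0 else 1.0
            if cosang < 0.5:  # direction swung by more than 60 degrees
                lrate *= 0.7
            else:
                lrate = min(lrate * 1.05, lrate_max)
        old_delta = delta
        if wchange < tol:
            converged = True
            break
    return W, converged, it


def fit_infomax(x, seed: int = 0, max_iter: int = 512, tol: float = 1e-7,
                lrate: float | None = None) -> ICADecomposition:
    """Fit Infomax ICA to a Recording or channels x samples matrix.

    Deterministic given ``seed``.  If the weight change does not fall below
    ``tol`` within ``max_iter`` sweeps the decomposition is still returned
    with ``converged=False`` and a warning.
    """
    data, fs, labels = _as_matrix(x)
    z, whitener, mean = center_whiten(data)
    k = z.shape[0]
    if lrate is None:
        lrate = 0.01 / np.log(k + 2.0)
    rng = np.random.default_rng(seed)
    W_sph, converged, n_iter = _infomax_core(z, rng, max_iter, tol, lrate)
    if not converged:
        warnings.warn(
            f"Infomax did not reach tol={tol} within {max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    W_full = W_sph @ whitener              # components x channels
    S = W_full @ (data - mean[:, None])
    # unit-variance source convention
    sd = S.std(axis=1)
    sd[sd == 0] = 1.0
    S /= sd[:, None]
    W_full /= sd[:, None]
    A = np.linalg.pinv(W_full)             # channels x components
    # sign convention: strongest mixing weight of each component positive
    flips = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    flips[flips == 0] = 1.0
    A *= flips[None, :]
    W_full *= flips[:, None]
    S *= flips[:, None]
    return ICADecomposition(
        A=A, W=W_full, S=S, mean=mean, whitener=whitener,
        converged=converged, n_iter=n_iter, seed=seed,
        fs=fs if fs is not None else float("nan"),
        labels=labels if labels is not None else [],
    )


def sources(decomp: ICADecomposition, x) -> np.ndarray:
    """Project data through the fitted unmixing transform: ``W @ (x - mean)``."""
    data, _, _ = _as_matrix(x)
    if data.shape[0] != decomp.n_channels:
        raise ValueError(
            f"decomposition was fitted on {decomp.n_channels} channels, "
            f"got {data.shape[0]}"
        )
    return decomp.W @ (data - decomp.mean[:, None])


def reconstruct(decomp: ICADecomposition, S_mod: np.ndarray,
                reject: set[int] | tuple[int, ...] = ()) -> Recording:
    """Inverse ICA: mix (possibly modified) sources back into channel space.

    Columns of the mixing matrix listed in ``reject`` are zeroed, which
    removes those components entirely.  With ``S_mod`` equal to the stored
    sources and no rejections, the original input is reproduced (exactly for
    full-rank or average-referenced data).
    """
    S_mod = np.asarray(S_mod, dtype=np.float64)
    if S_mod.shape != decomp.S.shape:
        raise ValueError(f"S_mod shape {S_mod.shape} != fitted {decomp.S.shape}")
    reject = sorted(set(int(j) for j in reject))
    if reject and (reject[0] < 0 or reject[-1] >= decomp.n_components):
        raise IndexError(f"reject indices {reject} out of range 0..{decomp.n_components - 1}")
    A = decomp.A.copy()
    if reject:
        A[:, reject] = 0.0
    data = A @ S_mod + decomp.mean[:, None]
    labels = decomp.labels or [f"ch{i}" for i in range(decomp.n_channels)]
    fs = decomp.fs if np.isfinite(decomp.fs) else 1.0
    return Recording(data=data, fs=fs, labels=labels, meta={"reconstructed": True})
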