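"""One-versus-rest common spatial patterns (CSP) for 3-class motor imagery.

For each binary problem (target class vs the pooled other two), CSP finds a
matrix ``P`` that simultaneously diagonalizes the two class covariances:

    P' R1 P = D   (diagonal, eigenvalues sorted descending)
    P' R2 P = I

i.e. the generalized symmetric eigenproblem ``R1 p = lambda R2 p``.  Per-trial
covariances are trace-normalized before averaging, so the filters are
invariant to global amplitude scaling.  The top two columns of each problem's
``P`` are transposed and stacked, in fixed class order (left, right, rest),
into the 6 x n_channels spatial filter ``Z``; applying it to an epoch ``X``
gives the six feature-channel signals ``S = Z X``.

The bank is exposed both as plain functions and as the scikit-learn
transformer :class:`OvrCspBank`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import CLASS_NAMES, DataError, EpochSet


class NumericalError(RuntimeError):
    """An eigenproblem is too ill-conditioned to solve reliably."""


@dataclasses.dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    n_trials_used: int
    normalization: str = "trace"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise DataError("covariance estimate is not symmetric")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-8 * max(w.max(), 1e-30):
            raise DataError("covariance estimate is not positive semi-definite")
        self.matrix = m


@dataclasses.dataclass
class CspSolution:
    P: np.ndarray          # eigenvector matrix, columns p_1 ... p_c
    D: np.ndarray          # eigenvalues, descending
    class_pair: tuple      # (target class, tuple of pooled classes)


@dataclasses.dataclass
class SpatialFilterBank:
    Z: np.ndarray                    # 6 x n_channels (2 rows per OVR problem)
    solutions: list[CspSolution]

    @property
    def n_channels(self) -> int:
        return self.Z.shape[1]


def trial_covariance(x: np.ndarray, trace_norm: bool = True) -> np.ndarray:
    """Covariance ``X X'`` of one epoch, optionally trace-normalized."""
    c = x @ x.T
    if trace_norm:
        tr = np.trace(c)
        if tr <= 0:
            raise DataError("epoch has zero energy")
        c = c / tr
    return c


def class_covariance(epochs: EpochSet, class_subset,
                     trace_norm: bool = True) -> CovarianceEstimate:
    """Mean over trials of per-trial (trace-normalized) covariances."""
    subset = np.atleast_1d(np.asarray(class_subset, dtype=np.int64))
    mask = np.isin(epochs.labels, subset)
    if mask.sum() < 1:
        names = [
            CLASS_NAMES[int(s)] if 0 <= int(s) < len(CLASS_NAMES) else str(int(s))
            for s in subset
        ]
        raise DataError(f"no trials for class(es) {names}")
    mats = [trial_covariance(x, trace_norm) for x in epochs.data[mask]]
    mean = np.mean(mats, axis=0)
    mean = (mean + mean.T) / 2.0
    return CovarianceEstimate(
        matrix=mean,
        n_trials_used=int(mask.sum()),
        normalization="trace" if trace_norm else "none",
    )


def _fix_signs(P: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(P), axis=0)
    signs = np.sign(P[idx, np.arange(P.shape[1])])
    signs[signs == 0] = 1.0
    return P * signs


def solve_csp(R1: np.ndarray, R2: np.ndarray,
              reg: float = 1e-9, class_pair=(None, None)) -> CspSolution:
    """Simultaneously diagonalize (R1, R2); eigenvalues descending.

    If ``R2`` is not strictly positive definite it is regularized by adding
    ``reg * trace(R2)/c * I`` before solving; a still-singular ``R2`` raises
    :class:`NumericalError`.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    c = R1.shape[0]
    tr = np.trace(R2)
    if np.linalg.eigvalsh(R2).min() <= 1e-10 * max(tr, 1e-30):
        R2 = R2 + reg * (tr / c if tr > 0 else 1.0) * np.eye(c)
        if np.linalg.eigvalsh(R2).min() <= 0:
            raise NumericalError(
                "R2 is singular; increase the regularization constant"
            )
    try:
        w, v = linalg.eigh(R1, R2)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "generalized eigendecomposition failed; R2 may need regularization"
        ) from exc
    order = np.argsort(w)[::-1]  # descending; ties keep input column order
    w, v = w[order], v[:, order]
    return CspSolution(P=_fix_signs(v), D=w, class_pair=class_pair)


def build_ovr_bank(epochs: EpochSet, reg: float = 1e-9,
                   n_components: int = 2) -> SpatialFilterBank:
    """Fit the stacked one-versus-rest bank on labeled epochs.

    For each class in fixed order (left, right, rest): ``R1`` is that class's
    covariance, ``R2`` the pooled covariance of the remaining two.  The top
    ``n_components`` (default 2) eigenvector columns per problem are stacked.
    """
    present = set(np.unique(epochs.labels).tolist())
    for code, name in enumerate(CLASS_NAMES):
        if code not in present:
            raise DataError(f"class {name!r} missing from training epochs")
    rows, solutions = [], []
    all_classes = tuple(range(len(CLASS_NAMES)))
    for target in all_classes:
        others = tuple(c for c in all_classes if c != target)
        R1 = class_covariance(epochs, [target]).matrix
        R2 = class_covariance(epochs, list(others)).matrix
        sol = solve_csp(R1, R2, reg=reg, class_pair=(target, others))
        solutions.append(sol)
        rows.append(sol.P[:, :n_components].T)
    return SpatialFilterBank(Z=np.vstack(rows), solutions=solutions)


def apply_bank(bank: SpatialFilterBank, epoch: np.ndarray) -> np.ndarray:
    """Feature-channel signals ``S = Z X`` for one epoch or a batch."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-2] != bank.n_channels:
        raise DataError(
            f"epoch has {epoch.shape[-2]} channels, bank expects "
            f"{bank.n_channels}"
        )
    return bank.Z @ epoch


class OvrCspBank(BaseEstimator, TransformerMixin):
    """scikit-learn transformer wrapping the OVR-CSP bank.

    Parameters
    ----------
    n_components : filters kept per binary problem (top eigenvectors).
    reg : relative ridge added to a near-singular pooled covariance.

    Attributes
    ----------
    bank_ : fitted :class:`SpatialFilterBank`.
    Z_ : the stacked spatial filter matrix (2*n_problems x n_channels).
    """

    def __init__(self, n_components: int = 2, reg: float = 1e-9):
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise DataError("X must be trials x channels x samples")
        epochs = EpochSet(
            data=X,
            labels=np.asarray(y, dtype=np.int64),
            sampling_rate=1.0,
            epoch_window=(0.0, X.shape[2]),
        )
        self.bank_ = build_ovr_bank(
            epochs, reg=self.reg, n_components=self.n_components
        )
        self.Z_ = self.bank_.Z
        return self

    def transform(self, X):
        check_is_fitted(self, "bank_")
        return apply_bank(self.bank_, np.asarray(X, dtype=float))
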