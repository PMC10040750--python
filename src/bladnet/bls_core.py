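"""Broad learning system numerics.

A broad learning system (BLS) is a flat network: input features are mapped by
random (optionally sparsity-refined) projections to *feature nodes* Z, which a
nonlinear random projection expands into *enhancement nodes* H. The state
matrix A = [Z | H | ...] collects all node outputs, and the only trained
parameters are the output weights W, solved in closed form by ridge
regression / pseudoinverse — no backpropagation.

The incremental updates are the point of the module: when new node columns
(an added BLS block) or new sample rows (added studies) are appended, the
cached Moore-Penrose pseudoinverse A+ and weights W are updated by the
Greville block recursion instead of re-solving from scratch, and the result
provably equals the batch solution. The update algebra is exact for the
pseudoinverse (ridge lambda -> 0) path; an exact positive-lambda head is
recomputed in closed form on request.

Notation: for A (n x m) with cached A+ (m x n), appending columns H_new gives

    D = A+ H_new,   C = H_new - A D,
    B = C+                          if C != 0,
        (I + D'D)^-1 D' A+          if C == 0,
    new A+ = [A+ - D B ; B],   new W = [W - D (B Y) ; B Y].

Row addition is the same recursion applied to A'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

logger = logging.getLogger(__name__)

__all__ = [
    "BLSBlock",
    "BLSState",
    "RidgeSolution",
    "random_feature_weights",
    "sparse_refine_weights",
    "make_block",
    "map_feature_nodes",
    "map_enhancement_nodes",
    "map_block",
    "ridge_solve",
    "pseudo_inverse",
    "build_state",
    "incremental_add_columns",
    "incremental_add_rows",
    "mp_violation",
]

# Greville degeneracy guard: max-abs threshold below which the residual block
# C is treated as zero and the (I + D'D)^-1 branch is taken.
C_ZERO_TOL = 1e-10


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Random projections


def random_feature_weights(d_in: int, n_nodes: int, seed: int = 0) -> np.ndarray:
    """(d_in + 1) x n_nodes weights, i.i.d. uniform on [-1, 1]; last row is bias."""
    if d_in < 1 or n_nodes < 1:
        raise ValidationError(f"dimensions must be positive, got d_in={d_in}, n_nodes={n_nodes}")
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(d_in + 1, n_nodes))


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def sparse_refine_weights(
    X: np.ndarray, W0: np.ndarray, lam_sae: float = 1e-3, iters: int = 20
) -> np.ndarray:
    """Refine random feature weights by an L1-sparse autoencoding fit (ISTA).

    Solves  min_W ||Xa W - Z0||_F^2 + lam_sae ||W||_1  where Xa = [X | 1] and
    Z0 = Xa W0 is the raw random projection. Initialisation is the
    least-squares solution (returned unchanged when ``iters`` = 0); each ISTA
    step uses the exact Lipschitz constant, so the objective never increases.
    """
    if iters < 0 or lam_sae < 0:
        raise ValidationError("iters and lam_sae must be non-negative")
    if not np.all(np.isfinite(X)):
        raise ValidationError("input matrix contains non-finite values")
    Xa = _augment(X)
    Z0 = Xa @ W0
    W = np.linalg.lstsq(Xa, Z0, rcond=None)[0]
    if iters == 0:
        return W
    L = np.linalg.norm(Xa, 2) ** 2
    if L == 0:
        return W
    step = 1.0 / L
    thresh = lam_sae * step
    for _ in range(iters):
        grad = 2.0 * (Xa.T @ (Xa @ W - Z0))
        V = W - step * grad
        W = np.sign(V) * np.maximum(np.abs(V) - thresh, 0.0)
    return W


def sae_objective(X: np.ndarray, W: np.ndarray, W0: np.ndarray, lam_sae: float) -> float:
    """Objective of :func:`sparse_refine_weights` at W (used by its tests)."""
    Xa = _augment(X)
    Z0 = Xa @ W0
    return float(np.sum((Xa @ W - Z0) ** 2) + lam_sae * np.abs(W).sum())


# ---------------------------------------------------------------------------
# Blocks


@dataclass
class BLSBlock:
    """One BLS block: feature-node weights Wf and enhancement weights We.

    Feature nodes are linear, Z = [X|1] Wf. Enhancement nodes are
    H = tanh(s [Z|1] We) with We orthonormalised and shrink scale s > 0, so
    every enhancement output lies in (-1, 1).
    """

    Wf: np.ndarray
    We: np.ndarray
    shrink: float = 0.8
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shrink <= 0:
            raise ValidationError(f"shrink must be positive, got {self.shrink}")
        if self.activation not in ("tanh", "sigmoid"):
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.We.shape[0] != self.Wf.shape[1] + 1:
            raise ValidationError(
                f"We rows ({self.We.shape[0]}) must equal n_feature_nodes+1 "
                f"({self.Wf.shape[1] + 1})"
            )

    @property
    def n_feature_nodes(self) -> int:
        return self.Wf.shape[1]

    @property
    def n_enhance_nodes(self) -> int:
        return self.We.shape[1]


def orthonormalize_columns(W: np.ndarray) -> np.ndarray:
    """Orthonormal columns via reduced QR; sign-fixed for determinism.

    When there are more columns than rows a strict orthonormal basis does not
    exist; columns are then only normalised (logged once per call).
    """
    rows, cols = W.shape
    if cols > rows:
        logger.info(
            "cannot orthonormalize %d columns in dimension %d; normalising instead", cols, rows
        )
        return W / np.linalg.norm(W, axis=0, keepdims=True)
    Q, R = np.linalg.qr(W)
    return Q * np.sign(np.diag(R))


def make_block(
    d_in: int,
    n_feature_nodes: int,
    n_enhance_nodes: int,
    seed: int = 0,
    shrink: float = 0.8,
    X: np.ndarray | None = None,
    sae_lam: float = 1e-3,
    sae_iters: int = 0,
) -> BLSBlock:
    """Build a block; if ``X`` is given and sae_iters > 0, Wf is sparsity-refined."""
    Wf = random_feature_weights(d_in, n_feature_nodes, seed=seed)
    if X is not None and sae_iters > 0:
        Wf = sparse_refine_weights(X, Wf, lam_sae=sae_lam, iters=sae_iters)
    We = random_feature_weights(n_feature_nodes, n_enhance_nodes, seed=seed + 1)
    We = orthonormalize_columns(We)
    return BLSBlock(Wf=Wf, We=We, shrink=shrink, seed=seed)


def map_feature_nodes(X: np.ndarray, block: BLSBlock) -> np.ndarray:
    """Z = [X|1] Wf (linear feature nodes)."""
    Xa = _augment(X)
    if Xa.shape[1] != block.Wf.shape[0]:
        raise ValidationError(
            f"input has {Xa.shape[1] - 1} columns, block expects {block.Wf.shape[0] - 1}"
        )
    return Xa @ block.Wf

def map_enhancement_nodes(Z: np.ndarray, block: BLSBlock) -> np.ndarray:
    """H = act(s [Z|1] We_orth); tanh keeps every entry in (-1, 1)."""
    Za = _augment(Z)
    if Za.shape[1] != block.We.shape[0]:
        raise ValidationError(
            f"feature nodes have {Za.shape[1] - 1} columns, block expects {block.We.shape[0] - 1}"
        )
    pre = block.shrink * (Za @ block.We)
    if block.activation == "tanh":
        return np.tanh(pre)
    return 1.0 / (1.0 + np.exp(-pre))


def map_block(X: np.ndarray, block: BLSBlock) -> np.ndarray:
    """Columns a block contributes to the state matrix: [Z | H]."""
    Z = map_feature_nodes(X, block)
    return np.hstack([Z, map_enhancement_nodes(Z, block)])


# ---------------------------------------------------------------------------
# Closed-form solves


@dataclass
class RidgeSolution:
    W: np.ndarray
    lam: float
    residual_norm: float


def ridge_solve(A: np.ndarray, Y: np.ndarray, lam: float = 0.0) -> RidgeSolution:
    """W = (A'A + lam I)^-1 A'Y; lam = 0 falls back to the minimum-norm
    pseudoinverse solution (defined for any rank)."""
    A = np.asarray(A, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if A.shape[0] != Y.shape[0]:
        raise ValidationError(f"A has {A.shape[0]} rows but Y has {Y.shape[0]}")
    if lam < 0:
        raise ValidationError(f"lam must be >= 0, got {lam}")
    if lam == 0.0:
        W = np.linalg.pinv(A) @ Y
    else:
        m = A.shape[1]
        W = sla.solve(A.T @ A + lam * np.eye(m), A.T @ Y, assume_a="pos")
    return RidgeSolution(W=W, lam=lam, residual_norm=float(np.linalg.norm(A @ W - Y)))


def pseudo_inverse(A: np.ndarray) -> np.ndarray:
    """Moore-Penrose pseudoinverse (SVD-based)."""
    return np.linalg.pinv(np.asarray(A, dtype=np.float64))


def mp_violation(A: np.ndarray, Ap: np.ndarray) -> float:
    """Largest absolute violation of the four Moore-Penrose conditions."""
    return max(
        float(np.abs(A @ Ap @ A - A).max(initial=0.0)),
        float(np.abs(Ap @ A @ Ap - Ap).max(initial=0.0)),
        float(np.abs((A @ Ap).T - A @ Ap).max(initial=0.0)),
        float(np.abs((Ap @ A).T - Ap @ A).max(initial=0.0)),
    )


# ---------------------------------------------------------------------------
# State and incremental updates


@dataclass
class BLSState:
    """State matrix A = [Z|H|...], cached pseudoinverse, and output weights."""

    A: np.ndarray
    A_pinv: np.ndarray
    W: np.ndarray
    lam: float = 0.0
    col_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_columns(self) -> int:
        return self.A.shape[1]


def build_state(A: np.ndarray, Y: np.ndarray, lam: float = 0.0,
                col_spans: list[tuple[int, int]] | None = None) -> BLSState:
    """Batch construction: cache A+ and solve W = A+ Y (pseudoinverse path)."""
    A = np.asarray(A, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    Ap = pseudo_inverse(A)
    return BLSState(
        A=A,
        A_pinv=Ap,
        W=Ap @ Y,
        lam=lam,
        col_spans=list(col_spans) if col_spans is not None else [(0, A.shape[1])],
    )


def _greville_append_column(
    A: np.ndarray, Ap: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, str]:
    """One exact Greville step: append column ``h`` to A with cached A+.

    Returns (A_new, Ap_new, d, b, branch) where b is the appended pseudo-
    inverse row. The two branches — h outside the current column space
    (residual c != 0) or inside it (c ~ 0) — are exhaustive per column, so
    the recursion is exact for any rank pattern of the added block.
    """
    h = h.reshape(-1, 1)
    d = Ap @ h
    c = h - A @ d
    scale = max(1.0, float(np.abs(h).max(initial=0.0)))
    if np.abs(c).max(initial=0.0) > C_ZERO_TOL * scale:
        b = c.T / float((c * c).sum())
        branch = "new-direction"
    else:
        b = (d.T @ Ap) / (1.0 + float((d * d).sum()))
        branch = "degenerate (c ~ 0)"
    Ap_new = np.vstack([Ap - d @ b, b])
    return np.hstack([A, h]), Ap_new, d, b, branch


def incremental_add_columns(state: BLSState, H_new: np.ndarray, Y: np.ndarray) -> BLSState:
    """Append node columns (a new block) by the Greville recursion.

    Columns are incorporated one at a time; per column the update is exact
    whether or not the column lies in the existing column space, so a block
    mixing dependent and independent columns (e.g. a later block's linear
    feature nodes, which share the input span of earlier blocks) is handled
    exactly. Equals the batch pseudoinverse solve on [A | H_new] without
    re-factorising old columns. ``Y`` is the training target matrix of the
    existing rows.
    """
    H_new = np.asarray(H_new, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if H_new.shape[0] != state.n_samples:
        raise ValidationError(
            f"H_new has {H_new.shape[0]} rows, state has {state.n_samples}"
        )
    A, Ap, W = state.A, state.A_pinv, state.W
    degenerate = 0
    for j in range(H_new.shape[1]):
        A, Ap, d, b, branch = _greville_append_column(A, Ap, H_new[:, j])
        bY = b @ Y
        W = np.vstack([W - d @ bY, bY])
        degenerate += branch.startswith("degenerate")
    logger.debug(
        "add_columns: %d -> %d columns (%d dependent)",
        state.n_columns, state.n_columns + H_new.shape[1], degenerate,
    )
    return BLSState(
        A=A,
        A_pinv=Ap,
        W=W,
        lam=state.lam,
        col_spans=state.col_spans + [(state.n_columns, state.n_columns + H_new.shape[1])],
    )


def incremental_add_rows(state: BLSState, A_x: np.ndarray, Y_x: np.ndarray) -> BLSState:
    """Append sample rows by the transposed Greville recursion.

    Each new study updates the weights by its own prediction error only:
    W <- W + b'(y_x - a_x W), where b is the appended pseudoinverse column
    of the transposed system.
    """
    A_x = np.asarray(A_x, dtype=np.float64)
    Y_x = np.asarray(Y_x, dtype=np.float64)
    if A_x.size == 0:
        return state
    if A_x.shape[1] != state.n_columns:
        raise ValidationError(
            f"A_x has {A_x.shape[1]} columns, state has {state.n_columns}"
        )
    At, Atp, W = state.A.T, state.A_pinv.T, state.W
    degenerate = 0
    for i in range(A_x.shape[0]):
        At, Atp, _, b, branch = _greville_append_column(At, Atp, A_x[i])
        W = W + b.T @ (Y_x[[i]] - A_x[[i]] @ W)
        degenerate += branch.startswith("degenerate")
    logger.debug(
        "add_rows: %d -> %d rows (%d dependent)",
        state.n_samples, state.n_samples + A_x.shape[0], degenerate,
    )
    return BLSState(
        A=At.T,
        A_pinv=Atp.T,
        W=W,
        lam=state.lam,
        col_spans=state.col_spans,
    )
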