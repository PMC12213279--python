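"""Linear-algebra helpers: standardisation, congruence, Procrustes alignment.

These primitives back the multiblock decomposition and every resampling
routine, so they are kept free of any dataset bookkeeping.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ZeroVarianceError


def standardize(X: np.ndarray, names=None, context: str = ""):
    """Column-wise z-scoring with ddof=1.

    Returns ``(Z, mean, sd)``. Raises :class:`ZeroVarianceError` naming the
    first constant column (correlations are undefined there).
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ZeroVarianceError(str(label), context)
    return (X - mean) / sd, mean, sd


def apply_standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardise ``X`` with externally supplied (e.g. training) statistics."""
    return (np.asarray(X, dtype=float) - mean) / sd


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def procrustes_rotation(V_ref: np.ndarray, V_new: np.ndarray) -> np.ndarray:
    """Orthogonal rotation Q minimising ||V_new @ Q - V_ref||_F.

    Q may include reflections, so sign flips are handled along with rotation.
    """
    U, _, Wt = np.linalg.svd(V_new.T @ V_ref)
    return U @ Wt


def rotate_svd(U: np.ndarray, s: np.ndarray, V: np.ndarray, V_ref: np.ndarray):
    """Align a resampled SVD triple to a reference via the right-side subspace.

    Returns ``(U_rot, s_rot, V_rot)`` where ``s_rot`` are the rotated singular
    values (column norms of ``U diag(s) Q``) and ``U_rot``/``V_rot`` are the
    rotated singular vectors. Aligning a solution to itself is the identity.
    """
    Q = procrustes_rotation(V_ref, V)
    US = U * s  # columns scaled
    rotated = US @ Q
    s_rot = np.linalg.norm(rotated, axis=0)
    return U @ Q, s_rot, V @ Q


def match_components(ref_vectors: np.ndarray, new_vectors: np.ndarray):
    """Greedy matching of new components to reference components.

    Both arguments are (n_variables, K) matrices of stacked salience vectors.
    For each reference component (in index order) the unmatched new component
    with maximal absolute Tucker congruence is chosen; ties break by index.
    Returns ``(index, sign)`` arrays of length K: new component ``index[i]``
    multiplied by ``sign[i]`` corresponds to reference component ``i``.
    """
    K_ref = ref_vectors.shape[1]
    K_new = new_vectors.shape[1]
    ref_n = ref_vectors / np.maximum(np.linalg.norm(ref_vectors, axis=0), 1e-300)
    new_n = new_vectors / np.maximum(np.linalg.norm(new_vectors, axis=0), 1e-300)
    C = ref_n.T @ new_n  # K_ref x K_new congruences
    index = np.empty(K_ref, dtype=int)
    sign = np.empty(K_ref, dtype=float)
    used = np.zeros(K_new, dtype=bool)
    for i in range(K_ref):
        order = np.argsort(-np.abs(C[i]), kind="stable")
        for j in order:
            if not used[j]:
                index[i] = j
                sign[i] = 1.0 if C[i, j] >= 0 else -1.0
                used[j] = True
                break
    return index, sign


def fix_svd_signs(U: np.ndarray, V: np.ndarray):
    """Resolve SVD sign indeterminacy: the max-|entry| of each left singular
    vector is made positive; the paired right vector flips with it."""
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip, V * flip
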