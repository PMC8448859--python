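import numpy as np
import pandas as pd
import pytest

from pdsubtype import CohortTable, ViewSpec, gaussian_kernel


def two_view_cohort_kernels(seed: int, separation: float = 5.0, n: int = 103):
    """Kernels for an informative 3-cluster view plus a pure-noise view."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1, 2], [60, 20, 23])[:n]
    centroids = np.array([[-1.0, 0.5, 0.0], [0.8, -1.0, 0.5], [0.5, 1.0, -1.0]]) * separation
    X_inf = centroids[labels] + rng.standard_normal((n, 3))
    X_noise = rng.standard_normal((n, 3))
    zs = lambda X: (X - X.mean(0)) / X.std(0, ddof=1)
    K_inf = gaussian_kernel(zs(X_inf), 1.0, view_name="informative")
    K_noise = gaussian_kernel(zs(X_noise), 1.0, view_name="noise")
    return K_inf, K_noise, labels


def small_cohort(n: int = 12, missing: dict | None = None) -> CohortTable:
    """Tiny deterministic cohort table for I/O and cleaning tests."""
    rng = np.random.default_rng(7)
    spec = ViewSpec(
        motor=["m1", "m2"],
        non_motor=["n1", "n2"],
        biomarker=["b1"],
        covariates=["age"],
        categorical=["sex"],
    )
    data = pd.DataFrame(
        {
            "m1": rng.normal(10, 2, n),
            "m2": rng.normal(5, 1, n),
            "n1": rng.normal(20, 4, n),
            "n2": rng.normal(3, 1, n),
            "b1": rng.normal(100, 10, n),
            "age": rng.normal(65, 5, n),
            "sex": rng.choice(["male", "female"], n),
        },
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id"),
    )
    for (row, col) in (missing or {}):
        data.iloc[row, data.columns.get_loc(col)] = np.nan
    return CohortTable(data=data, view_spec=spec)


def affine_projection_oracle(K: np.ndarray) -> np.ndarray:
    """Generic equality-constrained least squares via the KKT system.

    minimise ||S - K||^2 subject to S 1 = 1 and S' 1 = 1, solved over the
    vectorised matrix with Lagrange multipliers.
    """
    n = K.shape[0]
    I = np.eye(n)
    A_rows = np.kron(I, np.ones((1, n)))  # row sums of vec(S) (row-major)
    A_cols = np.kron(np.ones((1, n)), I)  # column sums
    A = np.vstack([A_rows, A_cols])
    m = A.shape[0]
    kkt = np.block([[np.eye(n * n), A.T], [A, np.zeros((m, m))]])
    rhs = np.concatenate([K.ravel(), np.ones(m)])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[: n * n].reshape(n, n)


def sinkhorn_oracle(K: np.ndarray, tol: float = 1e-12, max_iter: int = 200_000) -> np.ndarray:
    """Independent classical Sinkhorn balancing: alternate row/col normalisation."""
    S = np.asarray(K, dtype=float).copy()
    for _ in range(max_iter):
        S = S / S.sum(axis=1, keepdims=True)
        S = S / S.sum(axis=0, keepdims=True)
        if (
            np.abs(S.sum(axis=1) - 1).max() < tol
            and np.abs(S.sum(axis=0) - 1).max() < tol
        ):
            break
    return S


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated three-subtype synthetic cohort (shared, expensive)."""
    from pdsubtype import biofind_like_preset, generate_cohort

    spec = biofind_like_preset(separation=5.0, seed=0, with_proteins=False, with_items=False)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_search(separated_cohort):
    """Silhouette-tuned reference clustering of the separated cohort."""
    from pdsubtype import joint_search

    cohort, _ = separated_cohort
    return joint_search(cohort, n_trials=100, seed=0)
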