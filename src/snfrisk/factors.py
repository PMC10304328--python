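"""Exploratory factor analysis for claims and facility panels.

Fits an orthogonal factor model to the Pearson correlation matrix of
z-scored inputs by minimum-residual (unweighted least squares)
extraction, applies a varimax rotation with Kaiser normalization, and
assigns Thurstone (regression) factor scores to new rows using the
fit-sample standardization.  Model selection uses the Very Simple
Structure (VSS) criterion.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.optimize import linear_sum_assignment
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorModel",
    "FactorModelError",
    "average_person_indicators",
    "fit_factor_model",
    "vss_score",
    "vss_curve",
    "select_n_factors",
    "score_rows",
    "loading_report",
    "tucker_congruence",
    "align_factors",
]


class FactorModelError(ValueError):
    """Raised for degenerate inputs to the factor-analysis routines."""


@dataclass
class FactorModel:
    """A fitted orthogonal factor model.

    Attributes
    ----------
    variable_names : list of str
        Columns retained at fit time (zero-variance and duplicated
        columns are dropped before the correlation matrix is formed).
    loadings : (p, k) ndarray
        Varimax-rotated loading matrix; columns ordered by explained
        variance, signs fixed so the dominant loading is positive.
    uniquenesses : (p,) ndarray
        Per-variable unique variance, ``1 - communality``.
    correlation_matrix : (p, p) ndarray
    scoring_weights : (p, k) ndarray
        Thurstone regression weights ``W = R^{-1} Lambda``.
    mean_, sd_ : (p,) ndarray
        Fit-sample standardization reused when scoring new rows.
    vss_by_k : dict
        Very Simple Structure score per candidate k, populated when the
        model came out of :func:`select_n_factors`.
    """

    variable_names: list[str]
    n_factors: int
    loadings: np.ndarray
    uniquenesses: np.ndarray
    correlation_matrix: np.ndarray
    scoring_weights: np.ndarray
    mean_: np.ndarray
    sd_: np.ndarray
    method: str = "minres"
    rotation: str = "varimax"
    vss_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "variable_names": list(self.variable_names),
            "n_factors": int(self.n_factors),
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "correlation_matrix": self.correlation_matrix.tolist(),
            "scoring_weights": self.scoring_weights.tolist(),
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "method": self.method,
            "rotation": self.rotation,
            "vss_by_k": {str(k): v for k, v in self.vss_by_k.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            variable_names=d["variable_names"],
            n_factors=d["n_factors"],
            loadings=np.asarray(d["loadings"]),
            uniquenesses=np.asarray(d["uniquenesses"]),
            correlation_matrix=np.asarray(d["correlation_matrix"]),
            scoring_weights=np.asarray(d["scoring_weights"]),
            mean_=np.asarray(d["mean"]),
            sd_=np.asarray(d["sd"]),
            method=d.get("method", "minres"),
            rotation=d.get("rotation", "varimax"),
            vss_by_k={int(k): v for k, v in d.get("vss_by_k", {}).items()},
        )


def average_person_indicators(
    claims: pd.DataFrame, indicator_cols: list[str] | None = None
) -> pd.DataFrame:
    """Average binary indicators over each patient's set of claims.

    All claims are used, including rows flagged ``excluded``: exclusion
    applies to the outcome models, not to the averaging set used to
    build the factor model.  Returns one row per ``patient_id`` with
    entries in [0, 1].
    """
    if claims.empty:
        raise FactorModelError("claim table is empty")
    if indicator_cols is None:
        indicator_cols = [c for c in claims.columns if c.startswith("ind_")]
    if not indicator_cols:
        raise FactorModelError("no indicator columns found")
    vals = claims[indicator_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise FactorModelError("indicator columns must be strictly binary")
    return claims.groupby("patient_id")[indicator_cols].mean()


# ---------------------------------------------------------------------------
# Extraction


def _smc_start(R: np.ndarray) -> np.ndarray:
    """Starting uniquenesses from squared multiple correlations."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        smc = np.full(R.shape[0], 0.5)
    return np.clip(1.0 - smc, 0.01, 0.99)


def _truncated_loadings(S: np.ndarray, k: int) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    w_k = np.clip(w[-k:][::-1], 0.0, None)
    V_k = V[:, -k:][:, ::-1]
    return V_k * np.sqrt(w_k)


def _minres(R: np.ndarray, k: int) -> np.ndarray:
    """Minimum-residual extraction.

    Minimizes the Frobenius norm of ``R - Lambda Lambda' - diag(psi)``
    over psi, with Lambda the rank-k eigen-truncation of ``R - diag(psi)``.
    Because the diagonal is free, the minimum coincides with the
    classical off-diagonal least-squares (minres) criterion.  The
    concentrated objective has envelope gradient ``-2 diag(residual)``.
    """

    def objective(psi):
        S = R.copy()
        np.fill_diagonal(S, 1.0 - psi)
        lam = _truncated_loadings(S, k)
        resid = S - lam @ lam.T
        return float((resid**2).sum()), -2.0 * np.diag(resid)

    res = minimize(
        objective,
        x0=_smc_start(R),
        jac=True,
        method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * R.shape[0],
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    S = R.copy()
    np.fill_diagonal(S, 1.0 - res.x)
    return _truncated_loadings(S, k)


def _principal_axis(R: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-7) -> np.ndarray:
    """Principal-axis factoring with iterated communalities."""
    psi = _smc_start(R)
    for _ in range(max_iter):
        S = R.copy()
        np.fill_diagonal(S, 1.0 - psi)
        lam = _truncated_loadings(S, k)
        comm = np.clip((lam**2).sum(axis=1), 0.0, 0.999)
        psi_new = 1.0 - comm
        if np.max(np.abs(psi_new - psi)) < tol:
            psi = psi_new
            break
        psi = psi_new
    S = R.copy()
    np.fill_diagonal(S, 1.0 - psi)
    return _truncated_loadings(S, k)


def _varimax(L: np.ndarray, kaiser: bool = True) -> np.ndarray:
    if L.shape[1] < 2:
        return L
    h = np.sqrt(np.clip((L**2).sum(axis=1), 1e-12, None))
    A = L / h[:, None] if kaiser else L
    rotated, _T = rotate_factors(A, "varimax")
    if kaiser:
        rotated = rotated * h[:, None]
    return rotated


def _canonical_order(L: np.ndarray) -> np.ndarray:
    """Order factors by explained variance; make dominant loadings positive."""
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    return L


def _validate_columns(X: np.ndarray, names: list[str]):
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=3)
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    # Duplicated (perfectly correlated) columns make R singular.
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Z.T @ Z) / (len(X) - 1)
    dup_mask = np.ones(len(names), dtype=bool)
    p = len(names)
    for i in range(p):
        if not dup_mask[i]:
            continue
        for j in range(i + 1, p):
            if dup_mask[j] and abs(R[i, j]) > 1.0 - 1e-10:
                dup_mask[j] = False
    dup_dropped = [n for n, k in zip(names, dup_mask) if not k]
    if dup_dropped:
        warnings.warn(f"dropping duplicated columns: {dup_dropped}", stacklevel=3)
        X = X[:, dup_mask]
        names = [n for n, k in zip(names, dup_mask) if k]
    return X, names


def fit_factor_model(
    X,
    k: int,
    method: str = "minres",
    rotate: bool = True,
    kaiser: bool = True,
) -> FactorModel:
    """Fit a k-factor orthogonal model to the columns of ``X``.

    Columns are z-scored, the Pearson correlation matrix is formed,
    factors are extracted by minimum-residual least squares (or
    principal-axis when ``method='pa'``), and a varimax rotation with
    Kaiser normalization is applied.  Thurstone regression weights
    ``W = R^{-1} Lambda`` and the fit-sample standardization are stored
    so that new (e.g. visit-level) rows can be scored.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"v{i+1}" for i in range(arr.shape[1])]
    if k < 1:
        raise FactorModelError("k must be >= 1")
    if arr.shape[0] <= k:
        raise FactorModelError("need more rows than factors")
    arr, names = _validate_columns(arr, names)
    p = len(names)
    if k >= p:
        raise FactorModelError(f"k={k} >= number of usable variables ({p})")
    if k >= np.linalg.matrix_rank(arr - arr.mean(axis=0)):
        raise FactorModelError("k must be below the rank of the data matrix")

    mean_ = arr.mean(axis=0)
    sd_ = arr.std(axis=0, ddof=1)
    Z = (arr - mean_) / sd_
    R = (Z.T @ Z) / (arr.shape[0] - 1)
    np.fill_diagonal(R, 1.0)

    w = np.linalg.eigvalsh(R)
    if w.min() < 1e-10:
        if w.min() > -1e-8:
            # Smooth tiny negative eigenvalues from rounding.
            wv, V = np.linalg.eigh(R)
            R = (V * np.clip(wv, 1e-10, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        else:
            bad = set()
            off = R - np.eye(p)
            ii, jj = np.where(np.abs(off) > 0.999)
            for a, b in zip(ii, jj):
                bad.add(names[a])
                bad.add(names[b])
            raise FactorModelError(
                "correlation matrix is not positive definite; offending "
                f"columns: {sorted(bad) or 'unknown'}")

    if method == "minres":
        L = _minres(R, k)
    elif method == "pa":
        L = _principal_axis(R, k)
    else:
        raise FactorModelError(f"unknown extraction method {method!r}")

    if rotate:
        L = _varimax(L, kaiser=kaiser)
    L = _canonical_order(L)

    comm = np.clip((L**2).sum(axis=1), 0.0, 1.0)
    psi = 1.0 - comm
    W = np.linalg.solve(R, L)

    return FactorModel(
        variable_names=names,
        n_factors=k,
        loadings=L,
        uniquenesses=psi,
        correlation_matrix=R,
        scoring_weights=W,
        mean_=mean_,
        sd_=sd_,
        method=method,
        rotation="varimax" if rotate else "none",
    )


# ---------------------------------------------------------------------------
# Model selection


def vss_score(model: FactorModel, complexity: int = 1) -> float:
    """Very Simple Structure fit of the simplified loading matrix.

    Keeps, per variable, the ``complexity`` largest-|loading| entries,
    reproduces ``R* = S S'``, and returns
    ``1 - MS_offdiag(R - R*) / MS_offdiag(R)``.
    """
    k = model.n_factors
    if not (1 <= complexity <= k):
        raise FactorModelError(f"complexity must lie in [1, {k}]")
    L = model.loadings
    S = np.zeros_like(L)
    if complexity >= k:
        S = L.copy()
    else:
        idx = np.argsort(-np.abs(L), axis=1)[:, :complexity]
        rows = np.repeat(np.arange(L.shape[0]), complexity)
        S[rows, idx.ravel()] = L[rows, idx.ravel()]
    R = model.correlation_matrix
    mask = ~np.eye(R.shape[0], dtype=bool)
    denom = float((R[mask] ** 2).mean())
    if denom <= 1e-14:
        raise FactorModelError("off-diagonal correlations are all zero; VSS undefined")
    resid = R - S @ S.T
    return 1.0 - float((resid[mask] ** 2).mean()) / denom


def vss_curve(X, k_candidates, complexity: int = 1, method: str = "minres") -> dict[int, float]:
    """VSS score for each candidate number of factors."""
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise FactorModelError("empty candidate set")
    return {
        k: vss_score(fit_factor_model(X, k, method=method), complexity=min(complexity, k))
        for k in k_candidates
    }


def select_n_factors(X, k_candidates, complexity: int = 1, method: str = "minres") -> int:
    """Number of factors maximizing the VSS score; ties go to smaller k."""
    curve = vss_curve(X, k_candidates, complexity=complexity, method=method)
    best = max(curve, key=lambda k: (curve[k], -k))
    return best


# ---------------------------------------------------------------------------
# Scoring and reporting


def score_rows(model: FactorModel, rows) -> pd.DataFrame:
    """Thurstone factor scores for new rows sharing the model's variables.

    Rows are z-scored with the *fit-sample* means/SDs, then projected
    through ``W = R^{-1} Lambda``.  Works for visit-level binary rows
    even though the model was fit on person-averaged rows.
    """
    if isinstance(rows, pd.DataFrame):
        missing = [v for v in model.variable_names if v not in rows.columns]
        if missing:
            raise FactorModelError(f"rows are missing model variables: {missing}")
        arr = rows[model.variable_names].to_numpy(dtype=float)
        index = rows.index
    else:
        arr = np.asarray(rows, dtype=float)
        if arr.shape[1] != len(model.variable_names):
            raise FactorModelError(
                f"expected {len(model.variable_names)} columns, got {arr.shape[1]}")
        index = pd.RangeIndex(len(arr))
    Z = (arr - model.mean_) / model.sd_
    scores = Z @ model.scoring_weights
    cols = [f"f{j+1}" for j in range(model.n_factors)]
    return pd.DataFrame(scores, index=index, columns=cols)


def loading_report(model: FactorModel, threshold: float = 0.2) -> pd.DataFrame:
    """Loadings with |loading| > threshold, by factor then |loading| desc."""
    if threshold < 0:
        raise FactorModelError("threshold must be >= 0")
    rows = []
    for j in range(model.n_factors):
        col = model.loadings[:, j]
        sel = np.where(np.abs(col) > threshold)[0]
        sel = sel[np.argsort(-np.abs(col[sel]), kind="stable")]
        for i in sel:
            rows.append((j + 1, model.variable_names[i], float(col[i])))
    return pd.DataFrame(rows, columns=["factor", "variable", "loading"])


# ---------------------------------------------------------------------------
# Comparison utilities


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between loading columns."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer((A**2).sum(axis=0), (B**2).sum(axis=0)))
    return num / np.clip(den, 1e-12, None)


def align_factors(estimated: np.ndarray, true: np.ndarray):
    """Match estimated factors to true factors by congruence.

    Returns ``(perm, signs, congruences)`` such that
    ``estimated[:, perm] * signs`` best matches ``true`` column-wise;
    ``congruences[j]`` is the signed congruence of true factor j with its
    matched estimated factor.
    """
    C = tucker_congruence(estimated, true)  # (k_est, k_true)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(len(cols), dtype=int)
    signs = np.empty(len(cols))
    cong = np.empty(len(cols))
    for r, c in zip(rows, cols):
        perm[c] = r
        signs[c] = np.sign(C[r, c]) or 1.0
        cong[c] = abs(C[r, c])
    return perm, signs, cong
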