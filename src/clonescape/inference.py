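"""Matrix-correlation inference: Mantel, partial Mantel, causal modeling, MMRR.

All tests operate on the strictly-lower-triangle unfolding of labeled
distance matrices.  The permutation null is built by jointly permuting rows
and columns of one *matrix* (never the unfolded vector), which preserves the
dependence structure among entries sharing a population.  P-values use the
add-one estimator (1 + #exceedances) / (n_perm + 1) and so never report zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

_EPS = 1e-12
_PERM_CHUNK = 2048
_COND_LIMIT = 1e8

__all__ = [
    "unfold",
    "refold",
    "MantelResult",
    "MMRRResult",
    "CausalModelReport",
    "mantel",
    "partial_mantel",
    "mmrr",
    "causal_modeling",
]


def unfold(dm: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries in row-major order: d(2,1), d(3,1),
    d(3,2), ...; length n(n-1)/2."""
    values = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("unfold expects a square matrix")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("unfold expects a symmetric matrix")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("unfold expects a zero diagonal")
    i, j = np.tril_indices(values.shape[0], -1)
    return values[i, j]


def refold(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the symmetric zero-diagonal matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {vec.size} does not match n={n}")
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, -1)
    out[i, j] = vec
    out[j, i] = vec
    return out


def _check_aligned(mats: list[DistanceMatrix]) -> list[str]:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            extra = sorted(set(m.labels) ^ set(labels))
            raise ValueError(
                "distance matrices are not aligned; differing/missing labels: "
                f"{extra if extra else 'same set, different order'}"
            )
    return labels


def _permuted_unfolds(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Unfolded vectors of values[p][:, p] for each permutation p (P x m)."""
    i, j = np.tril_indices(values.shape[0], -1)
    return values[perms[:, i], perms[:, j]]


def _corr_many(v: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r between fixed vector v and each row of M."""
    vc = v - v.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum()) * np.sqrt((Mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Mc @ vc) / denom


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance unfolded vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _tail_count(stat_perm: np.ndarray, stat_obs: float, tail: str) -> int:
    if tail == "greater":
        return int(np.sum(stat_perm >= stat_obs - _EPS))
    if tail == "two-sided":
        return int(np.sum(np.abs(stat_perm) >= abs(stat_obs) - _EPS))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class MantelResult:
    """Simple or partial Mantel test outcome."""

    r: float
    p_value: float
    n_perm: int
    tail: str
    n: int
    covariates: list[str] = field(default_factory=list)


def mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation between the unfolded matrices, with a
    null built by jointly permuting rows and columns of B."""
    labels = _check_aligned([A, B])
    n = len(labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    a = unfold(A)
    b = unfold(B)
    r_obs = _pearson(a, b)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        p = min(_PERM_CHUNK, n_perm - done)
        perms = np.argsort(rng.random((p, n)), axis=1)
        r_perm = _corr_many(a, _permuted_unfolds(B.values, perms))
        exceed += _tail_count(r_perm, r_obs, tail)
        done += p
    p_value = (1 + exceed) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p_value, n_perm=n_perm, tail=tail, n=n)


def _residualizer(covs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [1, c1, c2, ...] and its pseudo-inverse, with a
    collinearity check."""
    Z = np.column_stack([np.ones(covs[0].size)] + covs)
    if np.linalg.cond(Z) > _COND_LIMIT:
        raise ValueError("covariates are (near-)collinear; condition number too large")
    return Z, np.linalg.pinv(Z)


def partial_mantel(
    A: DistanceMatrix,
    B: DistanceMatrix,
    covariates: list[DistanceMatrix],
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test: correlation between the residuals of A and of B
    after least-squares regression (with intercept) on the unfolded
    covariate matrices.

    The null permutes the focal matrix A (rows and columns jointly),
    re-residualizes it against the fixed covariates, and correlates with the
    fixed residuals of B — the residual-permutation variant.
    """
    labels = _check_aligned([A, B, *covariates])
    n = len(labels)
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 labels")
    if not 1 <= len(covariates) <= 2:
        raise ValueError("partial Mantel supports 1 or 2 covariates")
    a = unfold(A)
    b = unfold(B)
    Z, Zp = _residualizer([unfold(c) for c in covariates])
    res_a = a - Z @ (Zp @ a)
    res_b = b - Z @ (Zp @ b)
    # a matrix fully explained by the covariates leaves nothing to correlate
    if res_a.std() <= 1e-12 * max(a.std(), 1.0) or res_b.std() <= 1e-12 * max(b.std(), 1.0):
        r_obs = 0.0
    else:
        r_obs = _pearson(res_a, res_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        p = min(_PERM_CHUNK, n_perm - done)
        perms = np.argsort(rng.random((p, n)), axis=1)
        a_perm = _permuted_unfolds(A.values, perms)
        res_perm = a_perm - (a_perm @ Zp.T) @ Z.T
        r_perm = _corr_many(res_b, res_perm)
        exceed += _tail_count(r_perm, r_obs, tail)
        done += p
    p_value = (1 + exceed) / (n_perm + 1)
    return MantelResult(
        r=r_obs,
        p_value=p_value,
        n_perm=n_perm,
        tail=tail,
        n=n,
        covariates=[c.kind for c in covariates],
    )


@dataclass
class MMRRResult:
    """Multiple matrix regression with randomization.

    ``beta`` are the regression coefficients on z-scored predictors (and, by
    default, a z-scored response, making them standardized coefficients on
    the Mantel-r scale).  Per-coefficient p-values compare |t| against the
    permutation null; the overall F-test permutes the response matrix.
    """

    predictors: list[str]
    beta: np.ndarray
    t_stat: np.ndarray
    p_values: np.ndarray
    r_squared: float
    f_stat: float
    f_p_value: float
    intercept: float
    n_perm: int
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.predictors, "beta": self.beta, "t": self.t_stat, "p": self.p_values}
        )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance unfolded vector; cannot standardize")
    return (v - v.mean()) / sd


def mmrr(
    Y: DistanceMatrix,
    X: list[DistanceMatrix],
    n_perm: int = 10000,
    seed: int | None = None,
    scale_y: bool = True,
    names: list[str] | None = None,
) -> MMRRResult:
    """Multiple regression of one unfolded distance matrix on several others,
    with significance by randomization of the response matrix.

    Predictors are always z-scored; the response is z-scored too when
    ``scale_y`` is true (the default), which makes single-predictor beta
    identical to the simple Mantel r.  Set ``scale_y=False`` to keep
    coefficients in the response's own units.  Permutations shuffle the rows
    and columns of Y jointly and refit; per-coefficient tests are two-sided
    on t, the overall test is one-sided on F.
    """
    if not X:
        raise ValueError("MMRR needs at least one predictor")
    labels = _check_aligned([Y, *X])
    n = len(labels)
    m = n * (n - 1) // 2
    if names is None:
        names = [x.kind if x.kind != "generic" else f"X{i + 1}" for i, x in enumerate(X)]
    xs = [_zscore(unfold(x)) for x in X]
    k = len(xs)
    if k > 1:
        C = np.corrcoef(np.array(xs))
        if np.linalg.cond(C) > _COND_LIMIT:
            worst = np.unravel_index(np.argmax(np.abs(C - np.eye(k))), C.shape)
            raise ValueError(
                f"collinear predictors: {names[worst[0]]!r} and {names[worst[1]]!r}"
            )
    y_raw = unfold(Y)
    y = _zscore(y_raw) if scale_y else y_raw
    D = np.column_stack([np.ones(m)] + xs)
    DtD_inv = np.linalg.inv(D.T @ D)
    pinvD = DtD_inv @ D.T
    coef = pinvD @ y
    resid = y - D @ coef
    df_resid = m - k - 1
    sigma2 = float(resid @ resid) / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * np.diag(DtD_inv))
        # exact fit: zero residual variance makes t degenerate
        t_obs = np.where(
            se > 0,
            coef / np.where(se > 0, se, 1.0),
            np.where(np.abs(coef) > 1e-10, np.sign(coef) * np.inf, 0.0),
        )
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot
    f_obs = (r2 / k) / ((1 - r2) / df_resid) if r2 < 1.0 else np.inf

    rng = np.random.default_rng(seed)
    exceed_t = np.zeros(k, dtype=int)
    exceed_f = 0
    done = 0
    diag = np.diag(DtD_inv)
    while done < n_perm:
        p = min(_PERM_CHUNK, n_perm - done)
        perms = np.argsort(rng.random((p, n)), axis=1)
        Yp = _permuted_unfolds(Y.values, perms)
        if scale_y:
            # the unfolded multiset is permutation-invariant: same mean/sd
            Yp = (Yp - y_raw.mean()) / y_raw.std(ddof=1)
        Bp = pinvD @ Yp.T                       # (k+1) x P
        Rp = Yp.T - D @ Bp                      # m x P
        s2p = (Rp**2).sum(axis=0) / df_resid
        with np.errstate(invalid="ignore", divide="ignore"):
            Tp = Bp / np.sqrt(s2p[None, :] * diag[:, None])
            ssr = (Rp**2).sum(axis=0)
            sst = ((Yp - Yp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            r2p = 1.0 - ssr / sst
            Fp = (r2p / k) / ((1 - r2p) / df_resid)
        exceed_t += np.sum(np.abs(Tp[1:]) >= np.abs(t_obs[1:])[:, None] - _EPS, axis=1)
        exceed_f += int(np.sum(Fp >= f_obs - _EPS))
        done += p
    p_coef = (1 + exceed_t) / (n_perm + 1)
    f_p = (1 + exceed_f) / (n_perm + 1)
    return MMRRResult(
        predictors=list(names),
        beta=coef[1:],
        t_stat=t_obs[1:],
        p_values=p_coef,
        r_squared=r2,
        f_stat=f_obs,
        f_p_value=f_p,
        intercept=float(coef[0]),
        n_perm=n_perm,
        n=n,
    )


@dataclass
class CausalModelReport:
    """Full Mantel battery distinguishing candidate drivers of differentiation.

    ``table`` has one row per test (columns feature, controlled, r, p);
    ``verdicts`` maps each factor to supported / spurious / mixed /
    not_supported based on its simple test and all its partial tests at
    level alpha.
    """

    table: pd.DataFrame
    verdicts: dict[str, str]
    alpha: float
    n_perm: int
    seed: int | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def causal_modeling(
    gen: DistanceMatrix,
    dist: DistanceMatrix,
    barrier: DistanceMatrix,
    env: DistanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "greater",
) -> CausalModelReport:
    """Causal-modeling battery for isolation by distance vs environment vs
    barrier.

    Computes the simple Mantel test of genetic differentiation against each
    factor, each factor controlling each other factor singly (6 tests), and
    each factor controlling both others (3 tests).  A factor is "supported"
    when its simple test and *all* its partial tests are significant at
    alpha; "spurious" when the simple test is significant but no partial
    test is; "mixed" otherwise; "not_supported" when even the simple test is
    non-significant.
    """
    factors = {"dist": dist, "barrier": barrier, "env": env}
    _check_aligned([gen, dist, barrier, env])
    ss = np.random.SeedSequence(seed if seed is not None else np.random.SeedSequence().entropy)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(12))
    rows = []
    pvals: dict[tuple[str, str], float] = {}
    for name, M in factors.items():
        res = mantel(gen, M, n_perm=n_perm, seed=int(next(seeds)), tail=tail)
        rows.append({"feature": name, "controlled": "", "r": res.r, "p": res.p_value})
        pvals[(name, "")] = res.p_value
    for name, M in factors.items():
        others = [o for o in factors if o != name]
        for o in others:
            res = partial_mantel(gen, M, [factors[o]], n_perm=n_perm, seed=int(next(seeds)), tail=tail)
            rows.append({"feature": name, "controlled": o, "r": res.r, "p": res.p_value})
            pvals[(name, o)] = res.p_value
    for name, M in factors.items():
        others = [o for o in factors if o != name]
        res = partial_mantel(
            gen, M, [factors[o] for o in others], n_perm=n_perm, seed=int(next(seeds)), tail=tail
        )
        both = "+".join(others)
        rows.append({"feature": name, "controlled": both, "r": res.r, "p": res.p_value})
        pvals[(name, both)] = res.p_value
    verdicts = {}
    for name in factors:
        simple = pvals[(name, "")] <= alpha
        partials = [p for (f, c), p in pvals.items() if f == name and c != ""]
        sig = [p <= alpha for p in partials]
        if not simple:
            verdicts[name] = "not_supported"
        elif all(sig):
            verdicts[name] = "supported"
        elif not any(sig):
            verdicts[name] = "spurious"
        else:
            verdicts[name] = "mixed"
    return CausalModelReport(
        table=pd.DataFrame(rows), verdicts=verdicts, alpha=alpha, n_perm=n_perm, seed=seed
    )
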