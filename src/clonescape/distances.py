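"""The four distance matrices of the causal analysis.

Genetic differentiation (pairwise PhiPT from an AMOVA on dominant binary
data), geographic distance (great-circle km), environmental distance
(Euclidean in a reduced climate PCA space) and a binary barrier matrix, plus
the subsampling robustness check for PhiPT under small sample sizes.

PhiPT is the AMOVA analogue of Fst for dominant/binary markers: the fraction
of the total molecular variance (squared Euclidean distance between binary
profiles) attributable to differences among populations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform, cdist

from .genotypes import BinaryMatrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "AMOVAResult",
    "PhiPTPairwise",
    "PCAResult",
    "SubsampleReport",
    "geographic_distances",
    "environment_pca",
    "environmental_distances",
    "barrier_matrix",
    "amova_pair",
    "phi_pt_pairwise",
    "subsample_robustness",
]


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal.

    ``kind`` is one of ``genetic``, ``geographic``, ``environmental``,
    ``barrier`` (barrier matrices may only contain 0/1 off-diagonal).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        off = self.values[~np.eye(n, dtype=bool)]
        finite = off[~np.isnan(off)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("distance matrix must be non-negative")
        if self.kind == "barrier" and finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("barrier matrix entries must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reindex(self, labels: list[str]) -> "DistanceMatrix":
        """Reorder / subset to the given label order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([pos[lab] for lab in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("distance matrix file must have identical row and column labels")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# geographic / environmental / barrier


def geographic_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) between sites.

    ``coords`` is indexed by population with columns ``lat`` and ``lon`` in
    decimal degrees.  Uses the haversine formula on a sphere of radius
    6371 km, which is numerically stable for small separations.
    """
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitudes must be in [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitudes must be in [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix([str(x) for x in coords.index], d, "geographic")


@dataclass
class PCAResult:
    """PCA of a sites x variables environment table."""

    scores: np.ndarray           # sites x components
    variance_fraction: np.ndarray
    loadings: np.ndarray         # variables x components
    labels: list[str]
    variables: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


def environment_pca(env: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Principal components of the per-site environment table.

    Variables are centered and, by default, scaled to unit variance
    (correlation PCA) — climate variables come in incommensurable units.
    The sign of each component is fixed by making its largest-magnitude
    loading positive, so results are deterministic.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise ValueError("environment PCA needs at least 2 sites and 2 variables")
    if env.isna().any().any():
        raise ValueError("environment table contains missing values")
    X = env.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        bad = [str(v) for v, s in zip(env.columns, sd) if s == 0]
        if bad:
            raise ValueError(f"constant variable(s) cannot be standardized: {bad}")
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = S**2
    total = var.sum()
    frac = var / total if total > 0 else var
    return PCAResult(
        scores=U * S,
        variance_fraction=frac,
        loadings=Vt.T,
        labels=[str(x) for x in env.index],
        variables=[str(c) for c in env.columns],
    )


def environmental_distances(pca: PCAResult, n_axes: int = 2) -> DistanceMatrix:
    """Euclidean distance between sites on the first ``n_axes`` PCA scores."""
    if n_axes > pca.scores.shape[1]:
        raise ValueError(f"n_axes={n_axes} exceeds available components {pca.scores.shape[1]}")
    d = squareform(pdist(pca.scores[:, :n_axes]))
    return DistanceMatrix(list(pca.labels), d, "environmental")


def barrier_matrix(sides: pd.Series | dict) -> DistanceMatrix:
    """Binary barrier matrix: 0 for same-side pairs, 1 for opposite sides."""
    s = pd.Series(sides)
    if s.isna().any():
        missing = [str(i) for i in s.index[s.isna()]]
        raise ValueError(f"unlabeled population(s): {missing}")
    v = s.to_numpy()
    m = (v[:, None] != v[None, :]).astype(float)
    return DistanceMatrix([str(x) for x in s.index], m, "barrier")


# ---------------------------------------------------------------------------
# AMOVA / PhiPT


@dataclass
class AMOVAResult:
    """Two-group AMOVA variance decomposition on binary profiles."""

    phi_pt: float
    ss_among: float
    ss_within: float
    sigma2_among: float          # clamped at 0
    sigma2_among_raw: float      # unclamped component, for the record
    sigma2_within: float
    n0: float
    p_value: float | None
    n_perm: int
    n_columns: int


def _pair_complete_columns(x: np.ndarray) -> np.ndarray:
    """Columns with no missing entry across all rows of the pair."""
    return x[:, ~np.isnan(x).any(axis=0)]


def _ss_within_from_d2(d2: np.ndarray, group_sizes: tuple[int, int]) -> float:
    n1, _ = group_sizes
    s1 = d2[:n1, :n1].sum() / 2.0
    s2 = d2[n1:, n1:].sum() / 2.0
    return s1 / n1 + s2 / (d2.shape[0] - n1)


def amova_pair(
    x1: np.ndarray,
    x2: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> AMOVAResult:
    """AMOVA between two populations of binary profiles.

    Squared Euclidean distances between rows are partitioned as
    SS_total = (1/N) * sum_{i<j} d2_ij over all N rows, and
    SS_within = sum_k (1/n_k) * sum_{i<j in k} d2_ij.  With K = 2 groups,
    df_among = 1, df_within = N - 2, n0 = (N - sum n_k^2 / N) / (K - 1);
    sigma2_within = MS_within and sigma2_among = (MS_among - MS_within)/n0
    clamped at zero.  PhiPT = sigma2_among / (sigma2_among + sigma2_within),
    defined as 0 when both components vanish.  The permutation p-value
    shuffles individuals between the two populations (add-one estimator).

    Columns with missing data in any row of the pair are dropped first
    (pairwise-complete columns).
    """
    x = np.vstack([x1, x2])
    x = _pair_complete_columns(x)
    if x.shape[1] == 0:
        raise ValueError("no complete columns shared by the population pair")
    n1, n2 = len(x1), len(x2)
    N = n1 + n2
    if min(n1, n2) < 2:
        raise ValueError("each population needs at least 2 rows for AMOVA")
    d2 = cdist(x, x, metric="sqeuclidean")
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = _ss_within_from_d2(d2, (n1, n2))
    ss_among = ss_total - ss_within

    def _phi(ssw: float) -> tuple[float, float, float, float]:
        ssa = ss_total - ssw
        ms_among = ssa / 1.0
        ms_within = ssw / (N - 2)
        n0 = (N - (n1**2 + n2**2) / N) / 1.0
        s2w = ms_within
        s2a_raw = (ms_among - ms_within) / n0
        s2a = max(s2a_raw, 0.0)
        denom = s2a + s2w
        phi = s2a / denom if denom > 0 else 0.0
        return phi, s2a_raw, s2w, n0

    phi_obs, s2a_raw, s2w, n0 = _phi(ss_within)

    p_value = None
    if n_perm > 0:
        if rng is None:
            rng = np.random.default_rng()
        exceed = 0
        chunk = 512
        done = 0
        while done < n_perm:
            p = min(chunk, n_perm - done)
            perms = np.argsort(rng.random((p, N)), axis=1)
            g1 = perms[:, :n1]
            g2 = perms[:, n1:]
            s1 = d2[g1[:, :, None], g1[:, None, :]].sum(axis=(1, 2)) / 2.0 / n1
            s2 = d2[g2[:, :, None], g2[:, None, :]].sum(axis=(1, 2)) / 2.0 / n2
            ssw_perm = s1 + s2
            phi_perm = np.array([_phi(v)[0] for v in ssw_perm])
            exceed += int(np.sum(phi_perm >= phi_obs - 1e-12))
            done += p
        p_value = (1 + exceed) / (n_perm + 1)

    return AMOVAResult(
        phi_pt=phi_obs,
        ss_among=ss_among,
        ss_within=ss_within,
        sigma2_among=max(s2a_raw, 0.0),
        sigma2_among_raw=s2a_raw,
        sigma2_within=s2w,
        n0=n0,
        p_value=p_value,
        n_perm=n_perm,
        n_columns=x.shape[1],
    )


@dataclass
class PhiPTPairwise:
    """All pairwise PhiPT results among populations."""

    phi: DistanceMatrix
    p_values: pd.DataFrame | None
    results: dict[tuple[str, str], AMOVAResult]
    skipped: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.phi.to_csv(path)


def phi_pt_pairwise(
    bm: BinaryMatrix,
    populations: list[str],
    n_perm: int = 999,
    seed: int | None = None,
    min_size: int = 2,
) -> PhiPTPairwise:
    """Pairwise PhiPT matrix over all populations with >= ``min_size`` rows.

    Rows of ``bm`` are the units (pass genet representatives for a
    genet-level analysis).  Populations below ``min_size`` are skipped with a
    warning and excluded from the matrix.  ``n_perm = 0`` skips permutation
    p-values (point estimates only).
    """
    if len(populations) != len(bm.ids):
        raise ValueError("populations must parallel binary matrix rows")
    rng = np.random.default_rng(seed)
    by_pop: dict[str, list[int]] = {}
    for i, pop in enumerate(populations):
        by_pop.setdefault(pop, []).append(i)
    kept = [p for p, idx in by_pop.items() if len(idx) >= min_size]
    skipped = [p for p in by_pop if p not in kept]
    for p in skipped:
        logger.warning("population %s has < %d rows; skipped from PhiPT", p, min_size)
    if len(kept) < 2:
        raise ValueError("fewer than 2 populations eligible for pairwise PhiPT")
    K = len(kept)
    phi = np.zeros((K, K))
    pmat = np.full((K, K), np.nan)
    results: dict[tuple[str, str], AMOVAResult] = {}
    for (a, pa), (b, pb) in combinations(enumerate(kept), 2):
        res = amova_pair(bm.values[by_pop[pa]], bm.values[by_pop[pb]], n_perm=n_perm, rng=rng)
        phi[a, b] = phi[b, a] = res.phi_pt
        if res.p_value is not None:
            pmat[a, b] = pmat[b, a] = res.p_value
        results[(pa, pb)] = res
    phi_dm = DistanceMatrix(kept, phi, "genetic")
    p_df = pd.DataFrame(pmat, index=kept, columns=kept) if n_perm > 0 else None
    return PhiPTPairwise(phi=phi_dm, p_values=p_df, results=results, skipped=skipped)


# ---------------------------------------------------------------------------
# subsampling robustness


@dataclass
class SubsampleReport:
    """Stability of the PhiPT matrix under repeated small subsamples."""

    n_replicates: int
    subsample_size: int
    populations: list[str]
    r_values: np.ndarray
    mean_r: float
    sd_r: float

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "subsample_size": self.subsample_size,
            "populations": self.populations,
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
        }


def _matrix_correlation(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 and sv == 0:
        return 1.0 if np.allclose(u, v) else float("nan")
    if su == 0 or sv == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def subsample_robustness(
    bm: BinaryMatrix,
    populations: list[str],
    n_rep: int = 100,
    size: int = 6,
    min_rows: int = 11,
    seed: int | None = None,
) -> SubsampleReport:
    """Replicate the PhiPT matrix on random subsamples of ``size`` rows per
    eligible population (those with at least ``min_rows`` rows, i.e. more
    than 10 under the default) and correlate the replicate matrices.

    Reports the Pearson correlation of the unfolded PhiPT matrices for every
    replicate pair, with mean and sd.  High mean r indicates PhiPT is robust
    to the subsample size.
    """
    rng = np.random.default_rng(seed)
    by_pop: dict[str, list[int]] = {}
    for i, pop in enumerate(populations):
        by_pop.setdefault(pop, []).append(i)
    eligible = [p for p, idx in by_pop.items() if len(idx) >= min_rows]
    if len(eligible) < 2:
        raise ValueError(f"fewer than 2 populations with >= {min_rows} rows")
    iu = None
    unfolded = []
    for _ in range(n_rep):
        rows: list[int] = []
        pops_rep: list[str] = []
        for p in eligible:
            chosen = rng.choice(by_pop[p], size=size, replace=False)
            rows.extend(int(c) for c in chosen)
            pops_rep.extend([p] * size)
        sub = bm.subset_rows(rows)
        rep = phi_pt_pairwise(sub, pops_rep, n_perm=0)
        m = rep.phi.reindex(eligible).values
        if iu is None:
            iu = np.tril_indices(len(eligible), -1)
        unfolded.append(m[iu])
    r_values = np.array(
        [_matrix_correlation(unfolded[i], unfolded[j]) for i, j in combinations(range(n_rep), 2)]
    )
    return SubsampleReport(
        n_replicates=n_rep,
        subsample_size=size,
        populations=eligible,
        r_values=r_values,
        mean_r=float(np.nanmean(r_values)),
        sd_r=float(np.nanstd(r_values, ddof=1)) if len(r_values) > 1 else 0.0,
    )
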