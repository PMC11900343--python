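"""Population structure: IBS distances, VanRaden kinship, genotype PCA,
neighbor joining, and a K-ancestry admixture model fitted by EM.

The admixture model is the standard binomial mixture: individual *i* draws
each of its two alleles at site *j* from ancestral population *k* with
probability q_ik, and that population contributes an alternate allele with
probability f_kj, so the dosage g_ij ~ Binomial(2, h_ij) with
h_ij = Σ_k q_ik f_kj.  EM maximizes the binomial log-likelihood over Q
(rows on the simplex) and F (entries in [0, 1]); model choice over K uses
held-out binomial deviance on a random mask of genotype entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if np.nanmin(v, initial=0.0) < -1e-12:
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class GRM:
    ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 − mean identity-by-state similarity per sample pair.

    Per-site similarity between dosages d, e is 1 − |d − e| / 2 (1 for equal
    genotypes, 0.5 for one shared allele, 0 for opposite homozygotes),
    averaged over jointly non-missing sites.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = gm.dosages_float()
    V = ~np.isnan(X)
    X0 = np.nan_to_num(X)
    n = gm.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        joint = V[i][None, :] & V
        counts = joint.sum(axis=1)
        diff = np.abs(np.where(joint, X0 - X0[i][None, :], 0.0)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = np.where(counts > 0, diff / (2.0 * counts), np.nan)
    bad = np.argwhere(np.isnan(D) & ~np.eye(n, dtype=bool))
    if len(bad):
        pairs = {tuple(sorted((gm.sample_ids[a], gm.sample_ids[b]))) for a, b in bad}
        raise ValueError(f"sample pairs share no called sites: {sorted(pairs)}")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # remove float asymmetry
    return DistanceMatrix(ids=gm.sample_ids, values=D)


def grm_vanraden(gm: GenotypeMatrix) -> GRM:
    """VanRaden (method 1) genomic relationship matrix.

    G = Z Zᵀ / (2 Σ_j p_j(1 − p_j)) with Z the dosage matrix centered by 2p;
    missing dosages are replaced by 2p (zero after centering).
    """
    p = gm.alt_frequency()
    usable = np.isfinite(p)
    p = p[usable]
    X = gm.dosages_float()[:, usable]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all sites monomorphic: VanRaden denominator is zero")
    Z = np.nan_to_num(X - 2.0 * p[None, :], nan=0.0)
    # centering first, then zeroing NaN, implements the 2p imputation
    Z[np.isnan(X)] = 0.0
    G = Z @ Z.T / denom
    return GRM(ids=gm.sample_ids, values=G)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    ids: list[str]
    coordinates: np.ndarray  # samples × components
    variance_explained_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.coordinates[:, k]
                for k in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.ids, **cols})


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Genotype PCA with Patterson standardization.

    Dosages are centered by 2p and scaled by sqrt(2p(1−p)); missing values
    contribute zero after centering.  Eigen-decomposition of the resulting
    sample × sample covariance gives coordinates scaled by the square root of
    each eigenvalue; variance explained is relative to the sum of positive
    eigenvalues.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = gm.alt_frequency()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic sites")
    p = p[poly]
    X = gm.dosages_float()[:, poly]
    M = (X - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    M[np.isnan(X)] = 0.0
    C = M @ M.T / M.shape[1]
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    n_avail = int(pos.sum())
    if n_avail < n_components:
        warnings.warn(
            f"only {n_avail} positive eigenvalues; returning {n_avail} components"
        )
    k = min(n_components, n_avail)
    coords = vecs[:, :k] * np.sqrt(vals[:k])[None, :]
    var_pct = vals[:k] / vals[pos].sum() * 100.0
    return PCAResult(ids=gm.sample_ids, coordinates=coords,
                     variance_explained_pct=var_pct)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner}){self.name or ''}"


@dataclass
class Tree:
    root: TreeNode

    @property
    def newick(self) -> str:
        return self.root.newick()

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: TreeNode) -> None:
            if not n.children:
                out.append(n.name or "")
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return out

    def distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        leaves = self.leaf_names()
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        D = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if not node.children:
                return {index[node.name or ""]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child, length in node.children:
                cm = {k: v + length for k, v in walk(child).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for ia, da in child_maps[a].items():
                        for ib, db in child_maps[b].items():
                            D[ia, ib] = D[ib, ia] = da + db
            for cm in child_maps:
                below.update(cm)
            return below

        walk(self.root)
        return DistanceMatrix(ids=leaves, values=D)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at each step (ties broken
    by lowest index pair); branch lengths follow the standard formulas with
    negative estimates clamped to zero.  The final two nodes are joined by
    splitting their remaining distance equally.
    """
    D = np.asarray(dm.values, dtype=float)
    if np.abs(D - D.T).max(initial=0.0) > 1e-9:
        raise ValueError("input distance matrix is not symmetric")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    D = D.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # argmin is first minimum → lowest pair index
        ai, aj = divmod(int(flat), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for bk, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[ai, bk] + sub[aj, bk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    i, j = active
    d = max(D[i, j], 0.0)
    root = TreeNode(children=[(nodes[i], d / 2.0), (nodes[j], d / 2.0)])
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # samples × K ancestry fractions
    F: np.ndarray  # K × sites ancestral alt frequencies
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    cv_error: Optional[float] = None

    def q_frame(self, ids: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k + 1}" for k in range(self.K)])
        df.insert(0, "sample_id", list(ids))
        return df


_F_EPS = 1e-6


def _admixture_loglik(G: np.ndarray, W: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    H = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    G0 = np.where(W, G, 0.0)
    return float(np.sum(np.where(W, G0 * np.log(H) + (2.0 - G0) * np.log1p(-H), 0.0)))


def admixture_em(
    gm_or_dosages,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-ancestry admixture model by EM.

    Q rows start from a symmetric Dirichlet and F from Uniform(0.05, 0.95)
    under ``seed``; iteration stops when the log-likelihood improves by less
    than ``tol`` or after ``max_iter`` sweeps.  Missing genotypes contribute
    nothing to either the likelihood or the updates.
    """
    if isinstance(gm_or_dosages, GenotypeMatrix):
        G = gm_or_dosages.dosages_float()
    else:
        G = np.asarray(gm_or_dosages, dtype=float)
    n, J = G.shape
    if K < 1:
        raise ValueError("K must be ≥ 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    W = np.isfinite(G)
    G0 = np.where(W, G, 0.0)
    R0 = np.where(W, 2.0 - G, 0.0)  # reference-allele counts
    n_obs = W.sum(axis=1).astype(float)  # genotypes observed per sample
    if (n_obs == 0).any():
        raise ValueError("sample with no observed genotypes")

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, J))
    if K == 1:
        # closed form: Q ≡ 1, F = observed alt frequency
        Q = np.ones((n, 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = G0.sum(axis=0) / np.maximum((2.0 * W.sum(axis=0)), 1e-12)
        F = np.clip(freq, _F_EPS, 1 - _F_EPS)[None, :]
        ll = _admixture_loglik(G, W, Q, F)
        return AdmixtureFit(K=1, Q=Q, F=F, loglik=ll,
                            loglik_path=np.array([ll]), n_iter=0, converged=True)

    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        Hc = 1.0 - H
        A_sum = np.zeros((n, K))  # expected allele counts per ancestry
        F_num = np.zeros((K, J))
        F_den = np.zeros((K, J))
        for k in range(K):
            alt_k = Q[:, k][:, None] * F[k][None, :] / H * G0
            ref_k = Q[:, k][:, None] * (1.0 - F[k])[None, :] / Hc * R0
            A_sum[:, k] = alt_k.sum(axis=1) + ref_k.sum(axis=1)
            F_num[k] = alt_k.sum(axis=0)
            F_den[k] = alt_k.sum(axis=0) + ref_k.sum(axis=0)
        Q = A_sum / (2.0 * n_obs[:, None])
        Q = Q / Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(F_den > 0, F_num / np.maximum(F_den, 1e-300), F)
        F = np.clip(F, _F_EPS, 1 - _F_EPS)
        ll = _admixture_loglik(G, W, Q, F)
        path.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll

    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik=path[-1], loglik_path=np.array(path),
        n_iter=it, converged=converged,
    )


def admixture_cv(
    gm_or_dosages,
    K_range: Sequence[int],
    holdout_fraction: float = 0.10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[dict[int, float], int]:
    """Cross-validated choice of K.

    A random ``holdout_fraction`` of the non-missing genotype entries is
    masked; the model is fitted on the remainder for each K and scored by the
    mean binomial deviance between the held-out dosages g and their fitted
    expectations 2ĥ.  Returns (cv_error per K, argmin K); the same mask is
    used for every K so the comparison is paired.
    """
    if isinstance(gm_or_dosages, GenotypeMatrix):
        G = gm_or_dosages.dosages_float()
    else:
        G = np.asarray(gm_or_dosages, dtype=float)
    n, J = G.shape
    K_range = list(K_range)
    if any(k < 1 or k > n for k in K_range):
        raise ValueError(f"K_range {K_range} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(np.isfinite(G))
    n_hold = int(round(holdout_fraction * len(obs)))
    if n_hold == 0:
        raise ValueError("holdout fraction leaves no held-out entries")
    hold = obs[rng.choice(len(obs), size=n_hold, replace=False)]
    hi, hj = hold[:, 0], hold[:, 1]
    G_train = G.copy()
    G_train[hi, hj] = np.nan
    if not np.isfinite(G_train).any(axis=1).all():
        raise ValueError("holdout masked every genotype of some sample")

    g_held = G[hi, hj]
    errors: dict[int, float] = {}
    for K in K_range:
        fit = admixture_em(G_train, K, seed=seed + 1, max_iter=max_iter, tol=tol)
        h = np.clip((fit.Q @ fit.F)[hi, hj], 1e-9, 1 - 1e-9)
        errors[K] = float(np.mean(_binomial_deviance(g_held, h)))
    best = min(errors, key=lambda k: (errors[k], k))
    return errors, best


def _binomial_deviance(g: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Deviance of dosage g against Binomial(2, h), saturated-model form."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(g > 0, g * np.log(g / (2.0 * h)), 0.0)
        t2 = np.where(g < 2, (2.0 - g) * np.log((2.0 - g) / (2.0 - 2.0 * h)), 0.0)
    return 2.0 * (t1 + t2)
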