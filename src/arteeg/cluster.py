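"""Feature ranking, unsupervised embedding and clustering evaluation.

The analysis chain is: mRMR ranks features by mutual information with the
stimulus-class labels penalized by redundancy among selected features; the
top-k features feed an unsupervised extreme learning machine (random
orthonormalized sigmoid hidden layer whose output weights solve a
graph-Laplacian-regularized generalized eigenproblem); the low-dimensional
embedding is clustered with a Gaussian mixture model or k-means into three
classes; agreement with the known classes is scored with the Rand index.

Because the plain Rand index of two random balanced 3-partitions converges
to 5/9 rather than 1/3, the per-observation agreement accuracy (chance 1/3
for three classes) is reported alongside it everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import confusion_matrix
from sklearn.metrics.cluster import adjusted_rand_score, pair_confusion_matrix
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph


# ---------------------------------------------------------------------------
# mRMR

@dataclass
class FeatureRanking:
    order: list[str]
    scores: list[float]
    k: int

    @property
    def top(self) -> list[str]:
        return self.order[: self.k]


def discretize_three_level(x: np.ndarray) -> np.ndarray:
    """3-level discretization at mean +/- SD, the mRMR convention used here."""
    mu, sd = x.mean(), x.std()
    return np.digitize(x, [mu - sd, mu + sd])


def mutual_information_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two small-alphabet discrete arrays.

    Contingency-table estimate; agrees with sklearn's mutual_info_score and
    avoids its per-call overhead inside the greedy mRMR loop.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    cont = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    pij = cont / cont.sum()
    outer_p = pij.sum(axis=1, keepdims=True) * pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    return float(np.sum(pij[mask] * np.log(pij[mask] / outer_p[mask])))


def mrmr_select(table: pd.DataFrame, labels=None, k: int = 50,
                label_column: str = "class_label") -> FeatureRanking:
    """Greedy mRMR ranking (difference criterion: relevance - redundancy).

    ``table`` is a numeric feature frame, optionally holding the labels in
    ``label_column``. Deterministic given the discretization. A constant
    feature has zero relevance and is never picked ahead of an informative
    one.
    """
    if labels is None:
        if label_column not in table.columns:
            raise ValueError("labels missing: pass `labels` or include "
                             f"{label_column!r} in the table")
        labels = table[label_column].to_numpy()
        table = table.drop(columns=[label_column])
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    if k > table.shape[1]:
        raise ValueError("k exceeds the number of features")

    cols = list(table.columns)
    _, lab_codes = np.unique(labels, return_inverse=True)
    disc = {c: discretize_three_level(table[c].to_numpy(dtype=float)) for c in cols}
    relevance = np.array([mutual_information_discrete(lab_codes, disc[c])
                          for c in cols])

    selected: list[int] = []
    scores: list[float] = []
    redundancy = np.zeros(len(cols))
    remaining = set(range(len(cols)))
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in sorted(remaining):
            red = redundancy[j] / len(selected) if selected else 0.0
            score = relevance[j] - red
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.discard(best_j)
        for j in remaining:
            redundancy[j] += mutual_information_discrete(disc[cols[best_j]],
                                                         disc[cols[j]])
    return FeatureRanking([cols[j] for j in selected], scores, k=k)


# ---------------------------------------------------------------------------
# US-ELM

@dataclass
class ELMParams:
    """Settings for the unsupervised extreme learning machine.

    ``n_hidden`` sigmoid units; ``n_components`` (nλ) embedding dimensions;
    ``n_neighbors`` (k) of the similarity graph; ``reg`` (λ) trades the
    ridge penalty against the graph-smoothness penalty; ``sigma`` is the
    heat-kernel width (None = median pairwise distance).
    """

    n_hidden: int = 200
    n_components: int = 2
    n_neighbors: int = 7
    reg: float = 1.0
    sigma: float | None = None


def _orthonormal_weights(d: int, n_hidden: int, rng) -> np.ndarray:
    """Random (d x n_hidden) input weights, orthonormalized columnwise.

    At most ``d`` columns can be mutually orthonormal; wider layers are built
    from successive orthonormal blocks.
    """
    blocks = []
    remaining = n_hidden
    while remaining > 0:
        cols = min(d, remaining)
        q, _ = np.linalg.qr(rng.standard_normal((d, cols)))
        blocks.append(q)
        remaining -= cols
    return np.concatenate(blocks, axis=1)


def graph_laplacian(x: np.ndarray, n_neighbors: int,
                    sigma: float | None = None) -> np.ndarray:
    """Unnormalized Laplacian of the symmetrized heat-kernel kNN graph."""
    g = kneighbors_graph(x, n_neighbors=min(n_neighbors, len(x) - 1),
                         mode="distance", include_self=False)
    n_comp, _ = connected_components(g, directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN graph has {n_comp} components; the ridge term "
                      "regularizes across them", stacklevel=2)
    if sigma is None:
        dists = g.data[g.data > 0]
        sigma = float(np.median(dists)) if dists.size else 1.0
    w = g.toarray()
    mask = w > 0
    w[mask] = np.exp(-(w[mask] ** 2) / (2 * sigma ** 2))
    w = np.maximum(w, w.T)
    return np.diag(w.sum(axis=1)) - w


def uselm_embed(x: np.ndarray | pd.DataFrame, params: ELMParams,
                seed: int = 0) -> np.ndarray:
    """Embed observations via the unsupervised ELM eigenproblem.

    Inputs are z-scored; the hidden layer is a random orthonormalized sigmoid
    map; output weights are the generalized eigenvectors of
    (I + λ HᵀLH) v = γ HᵀH v for the smallest nontrivial eigenvalues.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < params.n_components + 1:
        raise ValueError("need at least n_components + 1 observations")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    w = _orthonormal_weights(d, params.n_hidden, rng)
    b = rng.uniform(-1.0, 1.0, params.n_hidden)
    h = 1.0 / (1.0 + np.exp(-(xz @ w + b)))

    lap = graph_laplacian(xz, params.n_neighbors, params.sigma)
    a = np.eye(params.n_hidden) + params.reg * (h.T @ lap @ h)
    bmat = h.T @ h + 1e-8 * np.eye(params.n_hidden)
    from scipy.linalg import eigh
    nev = params.n_components + 1
    evals, evecs = eigh(a, bmat, subset_by_index=[0, nev - 1])
    beta = evecs[:, 1:nev]                      # discard the trivial direction
    emb = h @ beta
    norms = np.linalg.norm(emb, axis=0)
    norms[norms == 0] = 1.0
    return emb / norms


# ---------------------------------------------------------------------------
# clustering + evaluation

@dataclass
class ClusteringResult:
    assignment: np.ndarray
    method: str
    rand_index: float
    agreement_accuracy: float
    adjusted_rand: float
    seed: int


def cluster_embedding(embedding: np.ndarray, labels=None,
                      method: str = "GMM", n_classes: int = 3,
                      seed: int = 0, n_restarts: int = 10) -> ClusteringResult:
    """Fit a 3-class GMM or k-means on the embedding; score against labels."""
    embedding = np.asarray(embedding, dtype=float)
    if len(embedding) < n_classes:
        raise ValueError("fewer observations than classes")
    if method.upper() == "GMM":
        model = GaussianMixture(n_components=n_classes, covariance_type="full",
                                n_init=n_restarts, max_iter=200, tol=1e-4,
                                reg_covar=1e-6, random_state=seed)
        assign = model.fit_predict(embedding)
    elif method.lower() in ("k-means", "kmeans"):
        model = KMeans(n_clusters=n_classes, n_init=n_restarts,
                       random_state=seed)
        assign = model.fit_predict(embedding)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    ri = acc = ari = np.nan
    if labels is not None:
        ri = rand_accuracy(assign, labels)
        acc = match_accuracy(assign, labels)
        ari = adjusted_rand_score(labels, assign)
    return ClusteringResult(assignment=assign, method=method, rand_index=ri,
                            agreement_accuracy=acc, adjusted_rand=ari, seed=seed)


def rand_accuracy(assignment, labels, adjusted: bool = False) -> float:
    """Plain Rand index: fraction of observation pairs on which the two
    partitions agree (same/different cluster). ``adjusted=True`` gives the
    chance-corrected version instead."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if assignment.shape != labels.shape:
        raise ValueError("length mismatch")
    if len(labels) < 2:
        raise ValueError("Rand index needs at least two observations")
    if adjusted:
        return float(adjusted_rand_score(labels, assignment))
    c = pair_confusion_matrix(labels, assignment)
    return float((c[0, 0] + c[1, 1]) / c.sum())


def match_accuracy(assignment, labels) -> float:
    """Per-observation agreement under the best cluster-to-class matching."""
    _, assignment = np.unique(np.asarray(assignment), return_inverse=True)
    _, labels = np.unique(np.asarray(labels), return_inverse=True)
    cm = confusion_matrix(labels, assignment)
    r, cidx = linear_sum_assignment(-cm)
    return float(cm[r, cidx].sum() / cm.sum())


def chance_accuracy(n: int = 3000, reps: int = 1000, n_classes: int = 3,
                    seed: int = 0) -> dict[str, float]:
    """Monte-Carlo chance level of a uniformly random assignment.

    Balanced labels of size ``n``; per repetition a uniform random
    assignment is scored by direct per-observation agreement (chance
    1/n_classes) and by the plain Rand index. Returns the means.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), n // n_classes)
    agree = np.empty(reps)
    rand = np.empty(reps)
    for r in range(reps):
        assign = rng.integers(0, n_classes, size=len(labels))
        agree[r] = np.mean(assign == labels)
        rand[r] = rand_accuracy(assign, labels)
    return {"agreement": float(agree.mean()), "rand": float(rand.mean()),
            "agreement_sd": float(agree.std()), "n": int(len(labels))}


# ---------------------------------------------------------------------------
# parameter search and summaries

@dataclass
class SearchResult:
    runs: pd.DataFrame
    best_params: ELMParams
    best_mean_rand: float
    chance_rand: float
    chance_agreement: float
    t_stat: float
    p_value: float


def parameter_search(
    x: np.ndarray | pd.DataFrame,
    labels,
    grid: dict | None = None,
    n_iter: int = 100,
    method: str = "GMM",
    n_classes: int = 3,
    seed: int = 0,
    n_hidden: int = 200,
) -> SearchResult:
    """Repeated random-hidden-layer runs over an (nλ, k, λ) grid.

    ``n_iter`` total iterations are spread round-robin over the grid
    configurations, each with a fresh random hidden layer and clustering
    seed. Reports the per-run accuracies, the best configuration by mean
    Rand index, a label-shuffled chance level, and a one-sample t test of
    the run accuracies against that chance level.
    """
    labels = np.asarray(labels)
    grid = grid or {"n_components": [2, 3], "n_neighbors": [5, 9],
                    "reg": [0.1, 1.0]}
    configs = [ELMParams(n_hidden=n_hidden, n_components=nc, n_neighbors=nn,
                         reg=rg)
               for nc in grid.get("n_components", [2])
               for nn in grid.get("n_neighbors", [7])
               for rg in grid.get("reg", [1.0])]
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * n_iter + 1)
    rows = []
    for it in range(n_iter):
        cfg = configs[it % len(configs)]
        emb = uselm_embed(x, cfg, seed=int(child[2 * it] % (2 ** 31)))
        res = cluster_embedding(emb, labels, method=method, n_classes=n_classes,
                                seed=int(child[2 * it + 1] % (2 ** 31)))
        rows.append({"iteration": it, "n_components": cfg.n_components,
                     "n_neighbors": cfg.n_neighbors, "reg": cfg.reg,
                     "rand": res.rand_index, "agreement": res.agreement_accuracy})
    runs = pd.DataFrame(rows)

    # chance by shuffling the labels against themselves
    rng = np.random.default_rng(int(child[-1] % (2 ** 31)))
    sh_rand, sh_agree = [], []
    for _ in range(200):
        perm = rng.permutation(labels)
        sh_rand.append(rand_accuracy(perm, labels))
        sh_agree.append(float(np.mean(perm == labels)))
    chance_rand = float(np.mean(sh_rand))
    chance_agree = float(np.mean(sh_agree))

    by_cfg = runs.groupby(["n_components", "n_neighbors", "reg"])["rand"].mean()
    nc, nn, rg = by_cfg.idxmax()
    best = ELMParams(n_hidden=n_hidden, n_components=int(nc),
                     n_neighbors=int(nn), reg=float(rg))
    t, p = stats.ttest_1samp(runs["rand"], chance_rand,
                             alternative="greater")
    return SearchResult(runs=runs, best_params=best,
                        best_mean_rand=float(by_cfg.max()),
                        chance_rand=chance_rand, chance_agreement=chance_agree,
                        t_stat=float(t), p_value=float(p))


def importance_summary(ranking: FeatureRanking, meta: pd.DataFrame,
                       k: int | None = None) -> dict[str, pd.Series]:
    """Percentage of the top-k features per channel and per band.

    Channel percentages sum to 100 over the montage; band percentages sum to
    100 over the five bands (broadband features excluded from the band
    denominator).
    """
    k = k or ranking.k
    if len(ranking.order) < k:
        raise ValueError("ranking shorter than k")
    top = ranking.order[:k]
    sub = meta.loc[top]
    channel_pct = (sub.groupby("channel").size() / k * 100.0)
    banded = sub[sub["band"] != "broadband"]
    band_pct = (banded.groupby("band").size() / max(len(banded), 1) * 100.0)
    return {"channel_pct": channel_pct.sort_values(ascending=False),
            "band_pct": band_pct.sort_values(ascending=False)}


def subject_clustergram(table: pd.DataFrame,
                        linkage_method: str = "ward") -> dict:
    """Hierarchical clustering of subjects on z-scored features (Fig.5 style).

    Returns the linkage tree and the first two-group cut with memberships.
    """
    if len(table) < 4:
        raise ValueError("need at least four subjects")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    link = hierarchy.linkage(z, method=linkage_method)
    cut = hierarchy.fcluster(link, t=2, criterion="maxclust")
    groups = {int(g): [str(s) for s, c in zip(table.index, cut) if c == g]
              for g in np.unique(cut)}
    return {"linkage": link, "cut": cut, "groups": groups,
            "subjects": list(table.index)}
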