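"""Enterotype discovery: sqrt-JSD distance, PAM, CH model selection, drivers.

The clustering route follows the classical enterotyping recipe: a
Jensen-Shannon-based metric between genus composition profiles, k-medoids
(PAM) partitions over a range of k, and the Calinski-Harabasz index on the
PCoA embedding to select the number of clusters. Driver genera are ranked by
random-forest permutation importance under repeated cross-validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import calinski_harabasz_score
from sklearn.model_selection import StratifiedKFold

from rumenet.community import DistanceMatrix, bray_curtis, pcoa
from rumenet.tables import AbundanceTable


@dataclasses.dataclass
class EnterotypeModel:
    distance_kind: str
    assignments: pd.Series  # sample -> cluster label (1-based, 1 = largest)
    medoid_ids: list[str]
    ch_curve: dict[int, float]
    k_opt: int
    cluster_sizes: dict[int, int]


@dataclasses.dataclass
class DriverRanking:
    table: pd.DataFrame  # genus_id, importance, cv_sd, rank

    def top(self, n: int = 9) -> pd.DataFrame:
        return self.table.head(n)


def jsd_matrix(tab: AbundanceTable, pseudocount: float = 1e-9) -> DistanceMatrix:
    """sqrt Jensen-Shannon divergence between relative-abundance profiles.

    Zeros are replaced by ``pseudocount`` times the mean row mass per cell and
    rows renormalized, so KL terms stay finite. Natural log; the maximum
    attainable distance is sqrt(ln 2).
    """
    rel = tab.rel_abundance
    if np.any(rel < 0):
        raise ValueError("negative abundances")
    eps = pseudocount * rel[rel > 0].mean() if np.any(rel > 0) else pseudocount
    p = np.where(rel > 0, rel, eps)
    p /= p.sum(axis=1, keepdims=True)
    logp = np.log(p)
    # JSD(a,b) = H(m) - (H(a)+H(b))/2 with m the midpoint; computed pairwise.
    n = tab.n_samples
    h = -(p * logp).sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (p[i] + p[i + 1:])
        hm = -(m * np.log(m)).sum(axis=1)
        jsd = hm - 0.5 * (h[i] + h[i + 1:])
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(np.maximum(jsd, 0.0))
    return DistanceMatrix(list(tab.sample_ids), out)


def pam_cluster(
    D: DistanceMatrix, k: int, seed: int | None = None
) -> tuple[np.ndarray, list[int]]:
    """k-medoids (PAM, BUILD + SWAP) on a precomputed distance matrix.

    Deterministic: BUILD greedily seeds medoids, SWAP accepts the single best
    improving swap per pass until no swap lowers the total distance to the
    nearest medoid. Ties break toward the lowest sample index. Returns
    (assignments as medoid-slot indices 0..k-1, medoid row indices).
    """
    n = D.n
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    d = D.values
    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gain = np.maximum(cur[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    medoids = sorted(medoids)
    # SWAP
    def objective(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best_obj = objective(medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            candidates = [h for h in range(n) if h not in medoids]
            for h in candidates:
                trial = medoids.copy()
                trial[mi] = h
                obj = objective(trial)
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_swap = (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            medoids = sorted(medoids)
            improved = True
    assign = np.argmin(d[:, medoids], axis=1)
    return assign, medoids


def ch_index(D: DistanceMatrix, assignments: np.ndarray) -> float:
    """Calinski-Harabasz index of a partition, on the PCoA embedding.

    Samples are embedded on the positive-eigenvalue PCoA axes so that
    between/within dispersion is well defined for an arbitrary metric.
    """
    labels = np.asarray(assignments)
    if np.unique(labels).size < 2:
        raise ValueError("CH index undefined for a single cluster")
    coords = pcoa(D).coordinates
    return float(calinski_harabasz_score(coords, labels))


def fit_enterotypes(
    tab: AbundanceTable,
    k_range: range | tuple = range(2, 11),
    distance_kind: str = "jsd",
    seed: int | None = None,
    pseudocount: float = 1e-9,
) -> EnterotypeModel:
    """Cluster samples into enterotypes and pick k by the CH criterion.

    Cluster labels are 1-based and ordered by descending cluster size.
    """
    if tab.n_genera < 2:
        raise ValueError("degenerate table: need at least two genera")
    ks = sorted(k_range)
    if tab.n_samples < max(ks) + 1:
        raise ValueError("not enough samples for requested k range")
    if distance_kind == "jsd":
        D = jsd_matrix(tab, pseudocount=pseudocount)
    elif distance_kind == "bray_curtis":
        D = bray_curtis(tab)
    else:
        raise ValueError(f"unknown distance_kind {distance_kind!r}")
    coords = pcoa(D).coordinates
    ch_curve: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, list[int]]] = {}
    for k in ks:
        assign, medoids = pam_cluster(D, k, seed=seed)
        fits[k] = (assign, medoids)
        ch_curve[k] = float(calinski_harabasz_score(coords, assign))
    k_opt = max(ch_curve, key=lambda k: (ch_curve[k], -k))
    assign, medoids = fits[k_opt]
    # relabel by descending size (1 = largest), stable tiebreak on old label
    sizes = pd.Series(assign).value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[a] for a in assign])
    return EnterotypeModel(
        distance_kind=distance_kind,
        assignments=pd.Series(labels, index=tab.sample_ids, name="enterotype"),
        medoid_ids=[tab.sample_ids[m] for m in medoids],
        ch_curve=ch_curve,
        k_opt=k_opt,
        cluster_sizes={lab: int((labels == lab).sum()) for lab in sorted(relabel.values())},
    )


def rank_driver_genera(
    tab: AbundanceTable,
    assignments: pd.Series | np.ndarray,
    n_repeats: int = 99,
    n_folds: int = 10,
    seed: int | None = None,
    n_trees: int = 200,
    n_perm: int = 5,
) -> DriverRanking:
    """Rank genera by random-forest permutation importance under repeated CV.

    A classifier (enterotype ~ genus relative abundances) is trained per CV
    fold per repeat; importance is the mean held-out permutation importance,
    with its SD across folds/repeats as ``cv_sd``.
    """
    y = np.asarray(assignments)
    if np.unique(y).size < 2:
        raise ValueError("need at least two enterotype clusters")
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError("each cluster must have at least n_folds samples")
    x = tab.rel_abundance
    rng = np.random.default_rng(seed)
    imps = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train, test in skf.split(x, y):
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(x[train], y[train])
            pi = permutation_importance(
                rf, x[test], y[test], n_repeats=n_perm,
                random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
            )
            imps.append(pi.importances_mean)
    imps = np.array(imps)
    df = pd.DataFrame({
        "genus_id": tab.genus_ids,
        "importance": imps.mean(axis=0),
        "cv_sd": imps.std(axis=0, ddof=1),
    })
    df = df.sort_values(["importance", "genus_id"], ascending=[False, True],
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return DriverRanking(df)
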