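"""Diversity metrics, distance matrices, ordination, and PERMANOVA."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _alpha

from rumenet.tables import AbundanceTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))


@dataclasses.dataclass
class PermanovaResult:
    term: str
    r_squared: float
    pseudo_f: float
    p_perm: float
    n_perm: int


@dataclasses.dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def rarefy_counts(
    tab: AbundanceTable, depth: int | str = "auto", seed: int | None = None
) -> AbundanceTable:
    """Subsample each sample without replacement to a fixed library size.

    ``depth='auto'`` uses the minimum library size. Samples with totals below
    an explicit depth are dropped with a warning.
    """
    counts = np.rint(tab.counts).astype(np.int64)
    totals = counts.sum(axis=1)
    if depth == "auto":
        depth_val = int(totals.min())
    else:
        depth_val = int(depth)
    if depth_val <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = totals >= depth_val
    if not keep.all():
        dropped = [tab.sample_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("rarefy_counts: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth_val, dropped)
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), tab.n_genera), dtype=np.int64)
    for r, i in enumerate(np.flatnonzero(keep)):
        out[r] = rng.multivariate_hypergeometric(counts[i], depth_val)
    return AbundanceTable(
        [tab.sample_ids[i] for i in np.flatnonzero(keep)], list(tab.genus_ids), out
    )


_ALPHA_METRICS = (
    "observed", "shannon", "simpson", "invsimpson", "pielou", "chao1", "ace",
    "fisher_alpha",
)


def alpha_diversity(tab: AbundanceTable, simpson_as_complement: bool = True) -> pd.DataFrame:
    """Per-sample alpha diversity profile.

    Shannon uses natural log. ``simpson`` is reported as 1 - sum(p^2) when
    ``simpson_as_complement`` (the common convention), else sum(p^2).
    All-zero samples get NaN across the board; Pielou is NaN for single-genus
    samples (ln 1 = 0).
    """
    rows = []
    for i in range(tab.n_samples):
        c = np.rint(tab.counts[i]).astype(np.int64)
        c = c[c > 0]
        if c.size == 0:
            rows.append({m: np.nan for m in _ALPHA_METRICS})
            continue
        p = c / c.sum()
        d = float(np.sum(p**2))
        try:
            ace = float(_alpha.ace(c, rare_threshold=10))
        except ValueError:  # e.g. all rare taxa are singletons
            ace = np.nan
        try:
            fisher = float(_alpha.fisher_alpha(c)) if c.size > 1 else np.nan
        except (ValueError, RuntimeError):
            fisher = np.nan
        row = {
            "observed": float(c.size),
            "shannon": float(_alpha.shannon(c, base=np.e)),
            "simpson": 1.0 - d if simpson_as_complement else d,
            "invsimpson": 1.0 / d,
            "pielou": float(_alpha.shannon(c, base=np.e) / np.log(c.size)) if c.size > 1 else np.nan,
            "chao1": float(_alpha.chao1(c, bias_corrected=True)),
            "ace": ace,
            "fisher_alpha": fisher,
        }
        rows.append(row)
    return pd.DataFrame(rows, index=tab.sample_ids)


def bray_curtis(tab: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on row-normalized relative abundances."""
    if tab.n_samples < 2:
        raise ValueError("need at least two samples")
    totals = tab.counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total sample(s) present; drop before bray_curtis")
    d = squareform(pdist(tab.rel_abundance, metric="braycurtis"))
    return DistanceMatrix(list(tab.sample_ids), d)


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposes -0.5 * J D^2 J; axes with non-positive eigenvalues are
    dropped from the coordinates but all eigenvalues are reported.
    """
    n = D.n
    d2 = D.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            logger.warning("pcoa: requested %d axes, only %d positive; truncating",
                           n_axes, coords.shape[1])
        coords = coords[:, :n_axes]
    return Ordination(list(D.ids), coords, evals)


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    levels = np.unique(groups)
    for g in levels:
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    k = levels.size
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(
    D: DistanceMatrix,
    groups: pd.Series | np.ndarray | dict,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[PermanovaResult]:
    """Marginal one-factor PERMANOVA per factor.

    ``groups`` may be a single factor (Series/array) or a mapping of term
    name -> factor; each factor is tested in its own single-term model.
    p = (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    if isinstance(groups, dict):
        terms = groups
    elif isinstance(groups, pd.DataFrame):
        terms = {c: groups[c] for c in groups.columns}
    else:
        terms = {"groups": groups}
    rng = np.random.default_rng(seed)
    d2 = D.values**2
    results = []
    for term, fac in terms.items():
        codes = pd.Categorical(np.asarray(fac)).codes
        if len(codes) != D.n:
            raise ValueError(f"factor {term!r} length mismatch")
        if np.unique(codes).size < 2:
            raise ValueError(f"factor {term!r} has fewer than two levels")
        f_obs, r2 = _permanova_f(d2, codes)
        exceed = 0
        for _ in range(n_perm):
            f_p, _ = _permanova_f(d2, rng.permutation(codes))
            if f_p >= f_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        results.append(PermanovaResult(term, float(r2), float(f_obs), float(p), n_perm))
    return results
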