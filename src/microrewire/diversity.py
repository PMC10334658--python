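"""Alpha and beta diversity: Shannon/Simpson, Bray-Curtis, PCoA, PERMANOVA.

Alpha diversity is computed per sample from relative abundances
(observed richness, Shannon entropy in nats, Gini-Simpson index); group
differences are tested with the Wilcoxon rank-sum test.  Beta diversity
uses Bray-Curtis dissimilarity, embedded by principal coordinates
analysis (classical MDS via Gower double-centering), with group effects
tested by PERMANOVA and variance homogeneity by a beta-dispersion ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from .differential_abundance import wilcoxon_rank_sum
from .feature_table import FeatureTable

ALPHA_METRICS = ("observed", "shannon", "simpson")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances sum to {p.sum()}, expected 1")
    return p


def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log by default)."""
    p = _check_proportions(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(p: np.ndarray, inverse: bool = False) -> float:
    """Gini-Simpson index D = 1 - sum p_i^2 (or inverse Simpson 1/sum p_i^2)."""
    p = _check_proportions(p)
    s = float((p ** 2).sum())
    return 1.0 / s if inverse else 1.0 - s


def alpha_table(ft: FeatureTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon and Simpson indices.

    Indices are computed on each sample's proportions over the taxa
    present in the table (columns of a merged, non-renormalized table
    are re-closed per sample before computing entropy).
    """
    if ft.mode != "relative":
        raise ValueError("alpha_table requires a relative-mode table")
    rows = []
    for s in ft.samples:
        col = ft.data[s].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            raise ValueError(f"sample {s!r} has zero total abundance")
        p = col / total
        rows.append((s, int((col > 0).sum()), shannon(p), simpson(p)))
    out = pd.DataFrame(rows, columns=["sample", "observed", "shannon",
                                      "simpson"]).set_index("sample")
    if ft.meta is not None:
        out["dataset"] = ft.meta.loc[out.index, "dataset"]
        out["group"] = ft.meta.loc[out.index, "group"]
    return out


def compare_alpha(alpha: pd.DataFrame,
                  groups: pd.Series | None = None) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of each alpha index between two groups."""
    if groups is None:
        if "group" not in alpha.columns:
            raise ValueError("no group assignment available")
        groups = alpha["group"]
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    a, b = labels
    if (groups == a).sum() < 1 or (groups == b).sum() < 1:
        raise ValueError("both groups must be nonempty")
    rows = []
    for metric in ALPHA_METRICS:
        x = alpha.loc[groups[groups == a].index, metric].to_numpy(float)
        y = alpha.loc[groups[groups == b].index, metric].to_numpy(float)
        w, p = wilcoxon_rank_sum(x, y)
        rows.append((metric, w, p))
    return pd.DataFrame(rows, columns=["metric", "statistic", "p"]
                        ).set_index("metric")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def bray_curtis(ft: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC_jk = sum|x_j - x_k| / sum(x_j + x_k)."""
    if ft.mode != "relative":
        raise ValueError("bray_curtis requires a relative-mode table")
    if len(ft.samples) < 2:
        raise ValueError("bray_curtis needs at least two samples")
    x = ft.values.T  # samples x taxa
    zero = np.where(x.sum(axis=1) == 0)[0]
    if zero.size >= 2:
        bad = [ft.samples[i] for i in zero]
        raise ValueError(f"all-zero samples make the denominator undefined: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ft.samples, d)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame       # samples x k axes
    eigenvalues: np.ndarray         # all n eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix, k: int) -> OrdinationResult:
    """Classical MDS: Gower-center -0.5*J*D^2*J and eigendecompose.

    Coordinates use only axes with positive eigenvalues (axes beyond
    them are zero-padded); negative eigenvalues are retained in the
    report but excluded from coordinates and explained proportions.
    """
    n = dm.n
    if not 1 <= k <= n - 1:
        raise ValueError(f"number of axes must be in [1, {n - 1}]")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # clamp numerical noise around zero
    eigvals[np.abs(eigvals) < 1e-10 * max(1.0, np.abs(eigvals).max())] = 0.0
    pos = eigvals > 0
    coords = np.zeros((n, k))
    usable = min(k, int(pos.sum()))
    coords[:, :usable] = eigvecs[:, :usable] * np.sqrt(eigvals[:usable])
    pos_sum = eigvals[pos].sum()
    prop = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else \
        np.zeros_like(eigvals)
    frame = pd.DataFrame(coords, index=dm.ids,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return OrdinationResult(frame, eigvals, prop)


@dataclass
class PermanovaResult:
    f: float
    r2: float
    p: float
    n_permutations: int
    seed: int


def _group_masks(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == g for g in np.unique(labels)]


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for mask in _group_masks(labels):
        m = int(mask.sum())
        if m > 1:
            ss += d2[np.ix_(mask, mask)].sum() / (2 * m)
    return ss


def permanova(dm: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F compares among-group to within-group sums of squared
    distances; the p-value is ``(#{F_perm >= F_obs} + 1) / (nperm + 1)``
    over random relabelings, deterministic under ``seed``.
    """
    labels = np.asarray(pd.Series(groups).reindex(dm.ids)
                        if isinstance(groups, (pd.Series, dict))
                        else groups)
    if labels.shape[0] != dm.n:
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n, a = dm.n, len(uniq)
    d2 = dm.values ** 2
    ss_t = d2.sum() / (2 * n)
    ss_w = _ss_within(d2, labels)
    ss_a = ss_t - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = labels[rng.permutation(n)]
        ss_w_p = _ss_within(d2, perm)
        f_p = ((ss_t - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(f=float(f_obs), r2=float(ss_a / ss_t), p=float(p),
                           n_permutations=n_permutations, seed=seed)


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to its own group centroid
    f: float
    p: float


def beta_dispersion(dm: DistanceMatrix, groups) -> DispersionResult:
    """Group dispersion around centroids in PCoA space, tested by ANOVA.

    Samples are embedded on all positive-eigenvalue axes; each sample's
    distance to its group centroid is the dispersion measure, compared
    across groups with a one-way ANOVA.
    """
    labels = np.asarray(pd.Series(groups).reindex(dm.ids)
                        if isinstance(groups, (pd.Series, dict))
                        else groups)
    if labels.shape[0] != dm.n:
        raise ValueError("group labels do not match the distance matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("beta dispersion requires at least two groups")
    ord_res = pcoa(dm, k=dm.n - 1)
    pos_axes = int((ord_res.eigenvalues > 0).sum())
    coords = ord_res.coordinates.to_numpy()[:, :max(pos_axes, 1)]
    dist = np.zeros(dm.n)
    for g in uniq:
        mask = labels == g
        if mask.sum() == 1:
            warnings.warn(f"group {g!r} has a single sample; its dispersion "
                          "contribution is 0", stacklevel=2)
            dist[mask] = 0.0
            continue
        centroid = coords[mask].mean(axis=0)
        dist[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)
    per_group = [dist[labels == g] for g in uniq]
    if all(np.ptp(arr) == 0 for arr in per_group):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = f_oneway(*per_group)
        if not (np.isfinite(f_stat) and np.isfinite(p)):
            # identical group dispersions up to rounding noise
            f_stat, p = max(float(f_stat), 0.0), 1.0
    return DispersionResult(pd.Series(dist, index=dm.ids, name="dispersion"),
                            float(f_stat), float(p))
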