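"""Planted-signal recovery measurements against synthetic ground truth.

These helpers run the analysis stages on simulated data and score the
results against the generator's ground truth: F1 of the gained/lost
edge sets, sensitivity for planted differential taxa, adjusted Rand
index for planted modules, and the empirical type-I error of the
PERMANOVA permutation test under a null of exchangeable labels.
"""

from __future__ import annotations

import numpy as np

from .cooccurrence import condition_network, differential_network
from .differential_abundance import diff_abundance_table
from .diversity import DistanceMatrix, permanova
from .feature_table import to_relative
from .synthetic_data import make_paper_like_spec, simulate
from .taxon_clustering import cluster_taxa


def f1_score(predicted: set, truth: set) -> float:
    """Harmonic mean of precision and recall of two edge sets."""
    if not predicted or not truth:
        return 0.0
    tp = len(predicted & truth)
    precision = tp / len(predicted)
    recall = tp / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two flat partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    cats_a, ia = np.unique(a, return_inverse=True)
    cats_b, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def edge_recovery(scale: float, seed: int, alpha: float = 0.05,
                  adjust: str = "BH") -> dict[str, float]:
    """Gained/lost F1 of the differential network on an edges-only spec.

    The generative condition follows the generator's contract for edge
    recovery: 10 case-only and 10 control-only latent pairs at |r| = 0.8
    and zero latent correlation elsewhere.
    """
    spec = make_paper_like_spec(scale, seed, n_modules=0, n_changed_edges=0)
    ft, truth = simulate(spec)
    rel = to_relative(ft)
    net_ctrl = condition_network(rel, "control", alpha=alpha, adjust=adjust,
                                 level="genus")
    net_case = condition_network(rel, "case", alpha=alpha, adjust=adjust,
                                 level="genus")
    dnet = differential_network(net_ctrl, net_case)
    return {
        "f1_gained": f1_score(dnet.edge_set("gained"), truth.expected_gained),
        "f1_lost": f1_score(dnet.edge_set("lost"), truth.expected_lost),
        "n_samples": len(rel.samples),
    }


def differential_sensitivity(scale: float, seed: int,
                             alpha: float = 0.05) -> dict[str, float]:
    """Fraction of planted mean-shift taxa flagged at BH FDR ``alpha``."""
    spec = make_paper_like_spec(scale, seed)
    ft, truth = simulate(spec)
    tab = diff_abundance_table(to_relative(ft), "genus", alpha=alpha)
    flagged = set(tab.index[tab["significant"]])
    sens = len(flagged & truth.differential_taxa) / len(truth.differential_taxa)
    return {"sensitivity": sens, "n_samples": len(ft.samples)}


def module_recovery(scale: float, seed: int,
                    min_pts: int = 4) -> dict[str, float]:
    """Adjusted Rand index of DBSCAN modules against planted membership.

    Profiles are standardized and eps comes from the (min_pts-1)-NN knee.
    """
    spec = make_paper_like_spec(scale, seed)
    ft, truth = simulate(spec)
    rel = to_relative(ft)
    assignment = cluster_taxa(rel, min_pts=min_pts, scale=True)
    truth_labels = [truth.modules[t] or "none" for t in rel.taxa]
    found_labels = [assignment.assignments[t] for t in rel.taxa]
    return {"ari": adjusted_rand_index(truth_labels, found_labels),
            "n_samples": len(rel.samples)}


def permanova_type1_error(n_replicates: int = 1000, n_samples: int = 12,
                          n_permutations: int = 199, seed: int = 0,
                          alpha: float = 0.05) -> dict[str, float]:
    """Empirical rejection rate of PERMANOVA under exchangeable labels."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    labels = np.array(["a"] * half + ["b"] * (n_samples - half))
    ids = [f"S{i}" for i in range(n_samples)]
    hits = 0
    from scipy.spatial.distance import pdist, squareform
    for rep in range(n_replicates):
        pts = rng.normal(size=(n_samples, 3))
        dm = DistanceMatrix(ids, squareform(pdist(pts)))
        res = permanova(dm, labels, n_permutations=n_permutations,
                        seed=int(rng.integers(2 ** 31)))
        hits += res.p <= alpha
    return {"type1_error": hits / n_replicates, "n": n_replicates}
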