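"""Per-condition Pearson co-occurrence networks and differential rewiring.

For each condition (case = tumor, control = normal tissue) every
unordered taxon pair is tested for Pearson correlation of relative
abundances across that condition's samples; statistically significant
correlations form the condition's co-occurrence network (non-significant
coefficients are retained in storage but treated as zero downstream).

The differential network compares the two condition networks edge by
edge:

* **gained** — significant in the case network only;
* **lost** — significant in the control network only;
* **changed_direction** — significant in both with opposite signs of r.

Pairs significant in both conditions with the same sign, or in neither,
are not rewired.  A node's rewiring degree is the number of rewired
edges incident to it; hub taxa are selected by degree cutoffs (>= 4 at
phylum level, > 15 at genus level; the family-level cutoff must be
configured).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential_abundance import bh_adjust
from .feature_table import FeatureTable

logger = logging.getLogger(__name__)

REWIRING_CLASSES = ("gained", "lost", "changed_direction")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided Student-t p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("Pearson test requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if 1.0 - r * r <= 0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def _pairwise_pearson(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation and p-value matrices for rows of ``x`` (taxa x samples)."""
    n = x.shape[1]
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


@dataclass
class CooccurrenceNetwork:
    """Undirected weighted graph of taxon-taxon Pearson associations."""

    condition: str
    level: str
    nodes: list[str]
    edges: pd.DataFrame  # taxon_a, taxon_b, r, p, q, significant
    alpha: float
    adjust: str

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def edge_lookup(self) -> dict[tuple[str, str], tuple[float, bool]]:
        out = {}
        for row in self.edges.itertuples(index=False):
            key = tuple(sorted((row.taxon_a, row.taxon_b)))
            out[key] = (row.r, bool(row.significant))
        return out


def condition_network(ft: FeatureTable, condition: str, alpha: float = 0.05,
                      adjust: str = "none",
                      level: str = "unspecified") -> CooccurrenceNetwork:
    """Build one condition's co-occurrence network from a relative table.

    All unordered pairs of non-constant taxa are tested; significance is
    judged on raw p-values at ``alpha`` or, with ``adjust='BH'``, on
    Benjamini-Hochberg q-values over all tested pairs at this level.
    Taxa constant within the condition are excluded with a logged notice.
    """
    if ft.mode != "relative":
        raise ValueError("condition_network requires a relative-mode table")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    sample_ids = ft.samples_in_group(condition)
    if len(sample_ids) < 4:
        raise ValueError(
            f"condition {condition!r} has {len(sample_ids)} samples; "
            "at least 4 are required"
        )
    if len(sample_ids) < 10:
        logger.warning("condition %r has only %d samples; correlation "
                       "estimates will be unstable", condition, len(sample_ids))
    x = ft.data[sample_ids].to_numpy(dtype=float)
    keep = np.ptp(x, axis=1) > 0
    dropped = [t for t, k in zip(ft.taxa, keep) if not k]
    if dropped:
        logger.info("excluding %d taxa constant in condition %r: %s",
                    len(dropped), condition, dropped)
    taxa = [t for t, k in zip(ft.taxa, keep) if k]
    x = x[keep]
    r_mat, p_mat = _pairwise_pearson(x)
    iu, ju = np.triu_indices(len(taxa), k=1)
    edges = pd.DataFrame({
        "taxon_a": [taxa[i] for i in iu],
        "taxon_b": [taxa[j] for j in ju],
        "r": r_mat[iu, ju],
        "p": p_mat[iu, ju],
    })
    if adjust == "BH":
        edges["q"] = bh_adjust(edges["p"].to_numpy())
        edges["significant"] = edges["q"] < alpha
    else:
        edges["q"] = np.nan
        edges["significant"] = edges["p"] < alpha
    return CooccurrenceNetwork(condition=condition, level=level, nodes=taxa,
                               edges=edges, alpha=alpha, adjust=adjust)


@dataclass
class DifferentialNetwork:
    """Rewired edges between the control and case networks."""

    level: str
    edges: pd.DataFrame  # taxon_a, taxon_b, class, r_control, r_case
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes and len(self.edges):
            self.nodes = sorted(
                set(self.edges["taxon_a"]) | set(self.edges["taxon_b"]))

    def edge_set(self, cls: str | None = None) -> set[tuple[str, str]]:
        e = self.edges if cls is None else \
            self.edges[self.edges["class"] == cls]
        return {tuple(sorted(p)) for p in zip(e["taxon_a"], e["taxon_b"])}


def differential_network(net_control: CooccurrenceNetwork,
                         net_case: CooccurrenceNetwork) -> DifferentialNetwork:
    """Classify every taxon pair as gained, lost or changed-direction.

    A pair untested in one condition (e.g. a taxon constant there)
    counts as non-significant in that condition.  The three classes
    partition the rewired edge set; same-sign pairs significant in both
    networks, and pairs significant in neither, are not rewired.
    """
    if net_control.level != net_case.level:
        raise ValueError(
            f"taxonomic levels differ: {net_control.level!r} vs "
            f"{net_case.level!r}"
        )
    ctrl = net_control.edge_lookup()
    case = net_case.edge_lookup()
    rows = []
    for pair in sorted(set(ctrl) | set(case)):
        r_ctrl, sig_ctrl = ctrl.get(pair, (np.nan, False))
        r_case, sig_case = case.get(pair, (np.nan, False))
        if sig_case and not sig_ctrl:
            cls = "gained"
        elif sig_ctrl and not sig_case:
            cls = "lost"
        elif sig_ctrl and sig_case and np.sign(r_ctrl) != np.sign(r_case):
            cls = "changed_direction"
        else:
            continue
        rows.append((pair[0], pair[1], cls, r_ctrl, r_case))
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "class",
                                        "r_control", "r_case"])
    return DifferentialNetwork(level=net_control.level, edges=edges)


def rewiring_degree(dnet: DifferentialNetwork) -> pd.DataFrame:
    """Per-node counts of incident rewired edges, by class and in total.

    Sorted by total degree descending with a stable taxon-name tiebreak.
    """
    counts: dict[str, dict[str, int]] = {}
    for a, b, cls in zip(dnet.edges["taxon_a"], dnet.edges["taxon_b"],
                         dnet.edges["class"]):
        for node in (a, b):
            c = counts.setdefault(node, {k: 0 for k in REWIRING_CLASSES})
            c[cls] += 1
    records = []
    for node, c in counts.items():
        total = sum(c.values())
        records.append((node, total, c["gained"], c["lost"],
                        c["changed_direction"]))
    out = pd.DataFrame(records, columns=["node", "total", "gained", "lost",
                                         "changed"])
    out = out.sort_values(["total", "node"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return out.set_index("node")


def hub_nodes(ctable: pd.DataFrame, level: str,
              family_cutoff: int | None = None) -> list[str]:
    """Degree-based hub selection, matching the per-level conventions.

    Phylum: degree >= 4; genus: degree > 15; family: the cutoff is not
    standardized and must be supplied (``family_cutoff``, inclusive).
    ``ctable`` must carry a ``degree`` column indexed by node.
    """
    if "degree" not in ctable.columns:
        raise ValueError("centrality table must have a 'degree' column")
    deg = ctable["degree"]
    if level == "phylum":
        sel = deg >= 4
    elif level == "genus":
        sel = deg > 15
    elif level == "family":
        if family_cutoff is None:
            raise ValueError("no standard family-level hub cutoff exists; "
                             "configure family_cutoff explicitly")
        sel = deg >= family_cutoff
    else:
        raise ValueError(f"unknown level {level!r}; expected phylum, family "
                         "or genus")
    return list(ctable.index[sel])
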