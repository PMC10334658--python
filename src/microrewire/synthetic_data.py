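"""Multi-dataset, two-condition compositional count simulator.

The generator emulates the statistical structure of a multi-study
case/control 16S survey: several datasets with their own sample sizes
and sequencing depths, two conditions (``case`` = tumor, ``control`` =
tumor-adjacent normal), compositional counts, and *planted* signal for
every downstream stage — group mean shifts (differential taxa), tight
taxon modules, and condition-specific pairwise correlations so that
gained / lost / changed-direction edges have known ground truth.

The generative family is logistic-normal / multinomial: per sample a
latent vector ``z ~ MVN(mu_group, diag(sigma) * Corr_group * diag(sigma))``
is drawn, proportions are ``softmax(z)``, and counts are multinomial at
the sample's sequencing depth.  Unlike a Dirichlet-multinomial this lets
arbitrary pairwise correlation signs be planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

Pair = tuple[str, str]

#: Case/control sample counts of the four emulated datasets at full scale
#: (totals 347 cases, 488 controls).
DATASET_SIZES = ((245, 231), (50, 207), (27, 26), (25, 24))


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class DatasetSpec:
    """One simulated study: name, group sizes and its depth range.

    Per-sample sequencing depth is drawn log-uniformly from
    ``[depth_min, depth_max]`` (a degenerate range gives fixed depth).
    """

    name: str
    n_case: int
    n_control: int
    depth_min: float
    depth_max: float

    def validate(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError(f"negative group size in dataset {self.name!r}")
        if not (0 < self.depth_min <= self.depth_max):
            raise ValueError(f"invalid depth range in dataset {self.name!r}")


@dataclass
class SyntheticSpec:
    """Full generative description of a simulated study collection."""

    taxa: list[str]
    datasets: list[DatasetSpec]
    mu_case: np.ndarray
    mu_control: np.ndarray
    sigma_scale: np.ndarray
    corr_case: np.ndarray
    corr_control: np.ndarray
    modules: dict[str, str | None]
    seed: int

    def validate(self) -> None:
        t = len(self.taxa)
        if len(set(self.taxa)) != t:
            raise ValueError("duplicate taxon names in spec")
        for arr, name in ((self.mu_case, "mu_case"),
                          (self.mu_control, "mu_control"),
                          (self.sigma_scale, "sigma_scale")):
            if np.asarray(arr).shape != (t,):
                raise ValueError(f"{name} must have length {t}")
        if (np.asarray(self.sigma_scale) <= 0).any():
            raise ValueError("sigma_scale entries must be positive")
        for mat, name in ((self.corr_case, "corr_case"),
                          (self.corr_control, "corr_control")):
            m = np.asarray(mat, dtype=float)
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} is not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError(f"{name} diagonal must be 1")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} is not positive semi-definite")
        for ds in self.datasets:
            ds.validate()

    # -- planted-structure accessors ------------------------------------
    def planted_edges(self, condition: str) -> dict[Pair, int]:
        """Taxon pairs with nonzero planted latent correlation (sign)."""
        corr = self.corr_case if condition == "case" else self.corr_control
        corr = np.asarray(corr)
        edges: dict[Pair, int] = {}
        t = len(self.taxa)
        for i in range(t):
            for j in range(i + 1, t):
                if corr[i, j] != 0:
                    edges[_pair(self.taxa[i], self.taxa[j])] = (
                        1 if corr[i, j] > 0 else -1
                    )
        return edges


@dataclass
class GroundTruth:
    """Extractable truth for every downstream stage of the pipeline."""

    differential_taxa: set[str]
    edges_case: dict[Pair, int]
    edges_control: dict[Pair, int]
    modules: dict[str, str | None]

    @property
    def expected_gained(self) -> set[Pair]:
        return set(self.edges_case) - set(self.edges_control)

    @property
    def expected_lost(self) -> set[Pair]:
        return set(self.edges_control) - set(self.edges_case)

    @property
    def expected_changed(self) -> set[Pair]:
        both = set(self.edges_case) & set(self.edges_control)
        return {p for p in both if self.edges_case[p] != self.edges_control[p]}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "differential_taxa": sorted(self.differential_taxa),
            "edges_case": [[a, b, s] for (a, b), s in
                           sorted(self.edges_case.items())],
            "edges_control": [[a, b, s] for (a, b), s in
                              sorted(self.edges_control.items())],
            "expected_gained": sorted(map(list, self.expected_gained)),
            "expected_lost": sorted(map(list, self.expected_lost)),
            "expected_changed": sorted(map(list, self.expected_changed)),
            "modules": {t: m for t, m in sorted(self.modules.items())},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            differential_taxa=set(doc["differential_taxa"]),
            edges_case={_pair(a, b): s for a, b, s in doc["edges_case"]},
            edges_control={_pair(a, b): s for a, b, s in doc["edges_control"]},
            modules=dict(doc["modules"]),
        )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def simulate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a counts-mode feature table (with metadata) and its ground truth.

    Sampling is deterministic under the spec's seed.  Each dataset uses
    an independent random stream derived from the master seed and the
    dataset's position, so regenerating one dataset is reproducible.
    """
    spec.validate()
    t = len(spec.taxa)
    sigma = np.asarray(spec.sigma_scale, dtype=float)
    cov = {
        "case": np.outer(sigma, sigma) * np.asarray(spec.corr_case, float),
        "control": np.outer(sigma, sigma) * np.asarray(spec.corr_control, float),
    }
    mu = {"case": np.asarray(spec.mu_case, float),
          "control": np.asarray(spec.mu_control, float)}
    # tiny jitter keeps the Cholesky factorization stable for PSD matrices
    jitter = 1e-10 * np.eye(t)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str]] = []
    for ds_idx, ds in enumerate(spec.datasets):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, ds_idx]))
        for group, n in (("case", ds.n_case), ("control", ds.n_control)):
            if n == 0:
                continue
            z = rng.multivariate_normal(mu[group], cov[group] + jitter,
                                        size=n, method="cholesky")
            props = _softmax(z)
            lo, hi = np.log(ds.depth_min), np.log(ds.depth_max)
            depths = np.exp(rng.uniform(lo, hi, size=n)).round().astype(int)
            depths = np.maximum(depths, 1)
            for i in range(n):
                sid = f"{ds.name}_{group}_{i:04d}"
                columns[sid] = rng.multinomial(depths[i], props[i])
                meta_rows.append((sid, ds.name, group))

    data = pd.DataFrame(columns, index=spec.taxa)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "dataset", "group"])
    meta = meta.set_index("sample_id")
    ft = FeatureTable(data, mode="counts", meta=meta)
    mu_diff = np.asarray(spec.mu_case) != np.asarray(spec.mu_control)
    truth = GroundTruth(
        differential_taxa={spec.taxa[i] for i in np.where(mu_diff)[0]},
        edges_case=spec.planted_edges("case"),
        edges_control=spec.planted_edges("control"),
        modules=dict(spec.modules),
    )
    return ft, truth


# ---------------------------------------------------------------------------
# Study-shaped default spec
# ---------------------------------------------------------------------------

def make_paper_like_spec(
    scale: float,
    seed: int,
    *,
    n_taxa: int = 64,
    n_case_edges: int = 10,
    n_control_edges: int = 10,
    n_changed_edges: int = 2,
    n_differential: int = 8,
    n_modules: int = 4,
    module_size: int = 5,
    latent_r: float = 0.8,
    module_rho: float = 0.9,
    shift: float = 1.0,
    sigma: float = 0.6,
    depth: float = 50_000.0,
    depth_spread: float = 2.0,
) -> SyntheticSpec:
    """Build a spec shaped like a four-study lung-biopsy collection.

    ``scale`` multiplies the per-dataset group sizes (scale 1 gives 347
    cases and 488 controls in total across the four datasets).  Planted
    structure occupies disjoint index blocks: condition-specific edge
    pairs for the case and control networks, a few sign-flipped
    (changed-direction) pairs, and correlated modules; differential
    taxa overlay the control-edge block with alternating +/- latent
    log-mean shifts.  Per-dataset depths are log-uniform in
    ``[depth/depth_spread, depth*depth_spread]``.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    datasets = []
    for k, (nc, nn) in enumerate(DATASET_SIZES, start=1):
        # round half away from zero, applied per dataset
        n_case = int(np.floor(scale * nc + 0.5))
        n_control = int(np.floor(scale * nn + 0.5))
        if n_case == 0 or n_control == 0:
            raise ValueError(
                f"scale {scale} empties a group of dataset {k}"
            )
        datasets.append(DatasetSpec(f"D{k}", n_case, n_control,
                                    depth / depth_spread,
                                    depth * depth_spread))

    need = 2 * (n_case_edges + n_control_edges + n_changed_edges) \
        + n_modules * module_size
    if need > n_taxa:
        raise ValueError(
            f"planted structure needs {need} taxa but only {n_taxa} requested"
        )
    taxa = [f"Genus{i + 1:02d}" for i in range(n_taxa)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10_000]))
    # Moderate spread of baseline log-means keeps the softmax denominator
    # spread across many taxa; a concentrated denominator would induce
    # closure correlations between latently independent taxa.
    mu_control = rng.normal(0.0, 0.4, size=n_taxa)
    mu_case = mu_control.copy()
    sigma_scale = np.full(n_taxa, float(sigma))
    corr_case = np.eye(n_taxa)
    corr_control = np.eye(n_taxa)

    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        idx = list(range(cursor, cursor + n))
        cursor += n
        return idx

    case_idx = take(2 * n_case_edges)
    ctrl_idx = take(2 * n_control_edges)
    chg_idx = take(2 * n_changed_edges)
    module_idx = take(n_modules * module_size)

    for e in range(n_case_edges):
        i, j = case_idx[2 * e], case_idx[2 * e + 1]
        r = latent_r if e % 2 == 0 else -latent_r
        corr_case[i, j] = corr_case[j, i] = r
    for e in range(n_control_edges):
        i, j = ctrl_idx[2 * e], ctrl_idx[2 * e + 1]
        r = latent_r if e % 2 == 0 else -latent_r
        corr_control[i, j] = corr_control[j, i] = r
    for e in range(n_changed_edges):
        i, j = chg_idx[2 * e], chg_idx[2 * e + 1]
        corr_control[i, j] = corr_control[j, i] = latent_r
        corr_case[i, j] = corr_case[j, i] = -latent_r

    modules: dict[str, str | None] = {t: None for t in taxa}
    for m in range(n_modules):
        letter = chr(ord("A") + m)
        members = module_idx[m * module_size:(m + 1) * module_size]
        for i in members:
            modules[taxa[i]] = letter
            # correlated blocks act as one large taxon in the softmax
            # denominator; keep their compositional weight modest
            mu_control[i] -= 1.0
            mu_case[i] -= 1.0
        for a in members:
            for b in members:
                if a != b:
                    corr_case[a, b] = corr_control[a, b] = module_rho

    # differential taxa overlay the control-edge block (mean shifts do not
    # perturb the planted correlation structure)
    diff_pool = ctrl_idx + case_idx + chg_idx
    if n_differential > len(diff_pool):
        raise ValueError("too many differential taxa requested")
    for k in range(n_differential):
        i = diff_pool[k]
        mu_case[i] = mu_control[i] + (shift if k % 2 == 0 else -shift)

    return SyntheticSpec(
        taxa=taxa,
        datasets=datasets,
        mu_case=mu_case,
        mu_control=mu_control,
        sigma_scale=sigma_scale,
        corr_case=corr_case,
        corr_control=corr_control,
        modules=modules,
        seed=seed,
    )
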