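"""Pipeline orchestration: config, stage execution, exports, manifest.

``run_pipeline`` drives the full analysis — merge (or simulate) →
diversity → differential abundance → DBSCAN modules → per-condition
co-occurrence networks → differential network → centralities — and
writes every table plus Cytoscape-readable network files to the output
directory, together with a JSON run manifest of seeds, input digests
and per-stage counts.  Outputs are deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cooccurrence import (condition_network, differential_network,
                           hub_nodes, rewiring_degree)
from .differential_abundance import diff_abundance_table, shapiro_wilk
from .diversity import (alpha_table, beta_dispersion, bray_curtis,
                        compare_alpha, pcoa, permanova)
from .feature_table import (FeatureTable, attach_metadata, collapse_taxa,
                            merge_shared, read_feature_table, read_metadata,
                            to_relative, write_feature_table)
from .graph_metrics import centrality_table
from .synthetic_data import make_paper_like_spec, simulate
from .taxon_clustering import cluster_taxa

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Flat configuration; every key mirrors a CLI flag."""

    # input: either explicit tables + metadata, or a synthetic spec
    tables: list[str] = field(default_factory=list)
    metadata: str | None = None
    synthetic_scale: float | None = None
    levels: list[str] = field(default_factory=lambda: ["genus"])
    renormalize: bool = False
    drop_unclassified: bool = False
    # edge testing
    edge_alpha: float = 0.05
    edge_adjust: str = "none"
    # diversity
    permanova_permutations: int = 999
    # clustering
    dbscan_eps: float | None = None
    dbscan_min_pts: int = 4
    dbscan_scale: bool = False
    # hubs
    family_hub_cutoff: int | None = None
    # misc
    seed: int = 0
    out_dir: str = "microrewire_out"
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.synthetic_scale is None:
            if not self.tables:
                raise ValueError("config needs input tables or a synthetic "
                                 "scale")
            for t in self.tables:
                if not Path(t).exists():
                    raise ValueError(f"input table not found: {t}")
            if self.metadata is None or not Path(self.metadata).exists():
                raise ValueError(f"metadata path not found: {self.metadata}")
        if self.edge_adjust not in ("none", "BH"):
            raise ValueError("edge_adjust must be 'none' or 'BH'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, force: bool, **kw) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; use force to overwrite")
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)


def export_network(dnet, ctable: pd.DataFrame, out_dir: str | Path,
                   prefix: str, force: bool = False) -> dict[str, str]:
    """Write SIF + edge/node attribute TSVs for Cytoscape import.

    The SIF file has one ``taxon_a pp taxon_b`` line per rewired edge;
    the edge-attribute TSV carries the rewiring class and the two
    condition correlations; the node-attribute TSV carries the
    centrality indices.  Rows are sorted for stable output.
    """
    if not len(dnet.edges):
        raise ValueError("cannot export an empty network")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out_dir / f"{prefix}.sif",
        "edges": out_dir / f"{prefix}.edges.tsv",
        "nodes": out_dir / f"{prefix}.nodes.tsv",
    }
    for p in paths.values():
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; use force to overwrite")
    edges = dnet.edges.sort_values(["taxon_a", "taxon_b"],
                                   kind="stable").reset_index(drop=True)
    with open(paths["sif"], "w") as fh:
        for a, b in zip(edges["taxon_a"], edges["taxon_b"]):
            fh.write(f"{a}\tpp\t{b}\n")
    edges.to_csv(paths["edges"], sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    ctable.to_csv(paths["nodes"], sep="\t", float_format=_FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def read_sif(path: str | Path) -> set[tuple[str, str]]:
    """Read a simple-interaction-format file back into an edge set."""
    edges = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                a, _, b = parts[0], parts[1], parts[2]
                edges.add(tuple(sorted((a, b))))
    return edges


def _load_input(cfg: PipelineConfig):
    """Return (per-level relative merged tables, truth-or-None, digests)."""
    digests = {}
    if cfg.synthetic_scale is not None:
        spec = make_paper_like_spec(cfg.synthetic_scale, cfg.seed)
        counts, truth = simulate(spec)
        rel = to_relative(counts)
        # synthetic tables are already at a single (genus-like) level
        return {lvl: rel for lvl in cfg.levels}, truth, digests

    meta = read_metadata(cfg.metadata)
    digests[str(cfg.metadata)] = _sha256(Path(cfg.metadata))
    raw = []
    for t in cfg.tables:
        ft = read_feature_table(t)
        digests[str(t)] = _sha256(Path(t))
        raw.append(attach_metadata(ft, meta))
    by_level = {}
    for level in cfg.levels:
        collapsed = []
        for ft in raw:
            c = ft
            if ft.lineages is not None:
                c = collapse_taxa(ft, level,
                                  drop_unclassified=cfg.drop_unclassified)
            collapsed.append(to_relative(c))
        by_level[level] = merge_shared(collapsed, renormalize=cfg.renormalize)
    return by_level, None, digests


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage per level; return (and write) the run manifest."""
    cfg.validate()
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "microrewire_version": __version__,
        # out_dir/force describe where this run landed, not what it computed
        "config": {k: v for k, v in asdict(cfg).items()
                   if k not in ("out_dir", "force")},
        "inputs": {},
        "levels": {},
    }
    stage = "load"
    try:
        tables, truth, digests = _load_input(cfg)
        manifest["inputs"] = digests
        for level, ft in tables.items():
            stage = f"level:{level}"
            manifest["levels"][level] = _run_level(cfg, level, ft, out_root)
        stage = "ground_truth"
        if truth is not None:
            truth.to_json(out_root / "ground_truth.json")
    except Exception as exc:
        manifest["status"] = "incomplete"
        manifest["failed_stage"] = stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    manifest["status"] = "complete"
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_level(cfg: PipelineConfig, level: str, ft: FeatureTable,
               out_root: Path) -> dict:
    out = out_root / level
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {"n_taxa": len(ft.taxa), "n_samples": len(ft.samples)}
    write_feature_table(ft, out / "merged.tsv", out / "metadata.tsv")

    # -- diversity -------------------------------------------------------
    logger.info("[%s] diversity analyses", level)
    alpha = alpha_table(ft)
    _write(alpha, out / "alpha.tsv", cfg.force)
    alpha_tests = compare_alpha(alpha)
    dm = bray_curtis(ft)
    _write(dm.to_frame(), out / "bray_curtis.tsv", cfg.force)
    ordination = pcoa(dm, k=min(3, dm.n - 1))
    _write(ordination.coordinates, out / "pcoa.tsv", cfg.force,
           index_label="sample")
    groups = ft.groups()
    perm = permanova(dm, groups, n_permutations=cfg.permanova_permutations,
                     seed=cfg.seed)
    disp = beta_dispersion(dm, groups)
    stats_rows = [("permanova_F", perm.f, perm.p),
                  ("permanova_R2", perm.r2, perm.p),
                  ("beta_dispersion_F", disp.f, disp.p)]
    for metric in alpha_tests.index:
        stats_rows.append((f"wilcoxon_{metric}",
                           alpha_tests.loc[metric, "statistic"],
                           alpha_tests.loc[metric, "p"]))
    _write(pd.DataFrame(stats_rows, columns=["test", "statistic", "p"]),
           out / "stats.tsv", cfg.force, index=False)
    counts["permanova_p"] = perm.p

    # -- differential abundance ------------------------------------------
    logger.info("[%s] differential abundance", level)
    da = diff_abundance_table(ft, level)
    _write(da, out / "differential_abundance.tsv", cfg.force)
    counts["significant_taxa"] = int(da["significant"].sum())

    # -- clustering -------------------------------------------------------
    logger.info("[%s] DBSCAN modules", level)
    assignment = cluster_taxa(ft, eps=cfg.dbscan_eps,
                              min_pts=cfg.dbscan_min_pts,
                              scale=cfg.dbscan_scale)
    _write(assignment.to_frame(), out / "modules.tsv", cfg.force)
    counts["modules"] = len(assignment.modules())

    # -- networks ---------------------------------------------------------
    logger.info("[%s] co-occurrence networks", level)
    nets = {}
    for condition in ("control", "case"):
        net = condition_network(ft, condition, alpha=cfg.edge_alpha,
                                adjust=cfg.edge_adjust, level=level)
        nets[condition] = net
        _write(net.edges, out / f"network_{condition}.tsv", cfg.force,
               index=False)
        counts[f"significant_edges_{condition}"] = \
            int(net.edges["significant"].sum())
    dnet = differential_network(nets["control"], nets["case"])
    counts["rewired_nodes"] = len(dnet.nodes)
    for cls in ("gained", "lost", "changed_direction"):
        counts[f"edges_{cls}"] = int((dnet.edges["class"] == cls).sum())
    logger.info("[%s] rewired network: %d nodes, %d edges", level,
                len(dnet.nodes), len(dnet.edges))
    if len(dnet.edges):
        ctable = centrality_table(dnet)
        rdeg = rewiring_degree(dnet)
        _write(rdeg, out / "rewiring_degree.tsv", cfg.force)
        export_network(dnet, ctable, out, "differential_network",
                       force=cfg.force)
        try:
            counts["hubs"] = hub_nodes(ctable, level,
                                       cfg.family_hub_cutoff)
        except ValueError:
            counts["hubs"] = None
    return counts
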