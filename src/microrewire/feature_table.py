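"""Taxon-by-sample feature tables: reading, validation, collapsing, merging.

The feature table is the pipeline's universal currency: a non-negative
taxa x samples matrix in either ``counts`` or ``relative`` mode, with
per-sample metadata (originating dataset and case/control group) and,
where available, a Greengenes-style taxonomic lineage per row.  All
downstream stages (diversity, differential abundance, clustering,
co-occurrence networks) consume this object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed lineage schema, kingdom -> species.  Collapsing is supported at
#: any of these ranks; the analyses in this package use phylum, family
#: and genus.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: QIIME/Greengenes rank prefixes ("k__Bacteria; p__Firmicutes; ...").
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

UNCLASSIFIED = "unclassified"
GROUPS = ("case", "control")


def parse_lineage(label: str) -> tuple[str, ...]:
    """Parse a semicolon-separated lineage string into a 7-tuple of rank names.

    Rank prefixes (``k__`` etc.) are stripped; missing or empty deeper
    ranks become empty strings.  Once a rank is unassigned every deeper
    rank is coerced to unassigned as well, so truncated lineages are
    well formed.
    """
    parts = [p.strip() for p in str(label).split(";")]
    names = []
    for i, part in enumerate(parts[: len(RANKS)]):
        for pref in _RANK_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        names.append(part.strip())
    names += [""] * (len(RANKS) - len(names))
    # enforce: unassigned implies all deeper ranks unassigned
    out = []
    seen_empty = False
    for name in names:
        if seen_empty or name == "":
            seen_empty = True
            out.append("")
        else:
            out.append(name)
    return tuple(out)


def _looks_like_lineage(label: str) -> bool:
    s = str(label)
    return ";" in s or any(s.startswith(p) for p in _RANK_PREFIXES)


@dataclass
class FeatureTable:
    """Taxa x samples abundance matrix with sample metadata.

    Parameters
    ----------
    data:
        DataFrame with taxon labels as the index and sample ids as
        columns; entries are counts or relative frequencies.
    mode:
        Either ``"counts"`` or ``"relative"``.
    meta:
        Optional per-sample metadata indexed by sample id with columns
        ``dataset`` and ``group`` (values ``case`` / ``control``).
    lineages:
        Optional mapping taxon label -> 7-tuple of rank names.
    """

    data: pd.DataFrame
    mode: str = "counts"
    meta: pd.DataFrame | None = None
    lineages: dict[str, tuple[str, ...]] | None = None
    #: False for relative tables restricted to shared taxa without
    #: renormalization, whose columns legitimately sum to < 1.
    closed: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def groups(self) -> pd.Series:
        if self.meta is None:
            raise ValueError("feature table has no sample metadata attached")
        return self.meta.loc[self.samples, "group"]

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups()
        return list(g.index[g == group])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        idx = self.data.index
        cols = self.data.columns
        dup_taxa = idx[idx.duplicated()].unique().tolist()
        if dup_taxa:
            raise ValueError(f"duplicate taxon labels: {dup_taxa}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("feature table contains non-numeric values")
        if np.isnan(vals.astype(float)).any():
            r, c = np.argwhere(np.isnan(vals.astype(float)))[0]
            raise ValueError(
                f"non-numeric value at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value {vals[r, c]} at taxon {idx[r]!r}, "
                f"sample {cols[c]!r}"
            )
        if self.mode == "relative" and self.closed and len(cols):
            sums = vals.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if bad.size:
                raise ValueError(
                    f"relative-mode sample {cols[bad[0]]!r} sums to "
                    f"{sums[bad[0]]}, expected 1"
                )
        if self.meta is not None:
            missing = [s for s in cols if s not in self.meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")
            bad_groups = sorted(
                set(self.meta.loc[list(cols), "group"]) - set(GROUPS)
            )
            if bad_groups:
                raise ValueError(
                    f"unknown group labels {bad_groups}; expected one of {GROUPS}"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from disk in counts mode.

    TSV dialect: first column holds taxon labels, header row holds
    sample ids, tab-separated numeric cells.  BIOM (JSON flavour) is
    accepted as a convenience; the canonical interchange format is TSV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dups:
        raise ValueError(f"duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = sample_ids  # undo any pandas de-duplication mangling
    dup_taxa = df.index[df.index.duplicated()].unique().tolist()
    if dup_taxa:
        raise ValueError(f"duplicate taxon labels: {dup_taxa}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            taxon = df.index[coerced.isna()][0]
            raise ValueError(
                f"non-numeric value at taxon {taxon!r}, sample {col!r}"
            )
        df[col] = coerced
    lineages = None
    if any(_looks_like_lineage(t) for t in df.index):
        lineages = {t: parse_lineage(t) for t in df.index}
    return FeatureTable(df, mode="counts", lineages=lineages)


def _read_biom_json(path: Path) -> FeatureTable:
    """Minimal reader for the BIOM 1.0 JSON flavour (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    n_r, n_c = doc["shape"]
    mat = np.zeros((n_r, n_c))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    df = pd.DataFrame(mat, index=rows, columns=cols)
    lineages = {}
    for r in doc["rows"]:
        tax = (r.get("metadata") or {}).get("taxonomy")
        if tax:
            lineages[r["id"]] = parse_lineage(";".join(tax))
    return FeatureTable(df, mode="counts", lineages=lineages or None)


def write_feature_table(ft: FeatureTable, path: str | Path,
                        meta_path: str | Path | None = None) -> None:
    """Write a table as TSV, optionally with a sidecar metadata TSV."""
    ft.data.to_csv(path, sep="\t", index_label="taxon", float_format="%.10g")
    if meta_path is not None:
        if ft.meta is None:
            raise ValueError("no metadata to write")
        out = ft.meta.loc[ft.samples].reset_index()
        out.columns = ["sample_id"] + list(out.columns[1:])
        out.to_csv(meta_path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, dataset, group."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "dataset", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def attach_metadata(ft: FeatureTable, meta: pd.DataFrame) -> FeatureTable:
    """Bind sample metadata (``sample_id``, ``dataset``, ``group``) to a table.

    Every sample in the table must appear exactly once in ``meta`` and
    carry a group label in ``{case, control}``.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    counts = meta.index.value_counts()
    dups = counts.index[counts > 1].tolist()
    dups = [d for d in dups if d in ft.samples]
    if dups:
        raise ValueError(f"samples appear more than once in metadata: {dups}")
    missing = [s for s in ft.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    bound = meta.loc[ft.samples, ["dataset", "group"]].copy()
    bad = sorted(set(bound["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected one of {GROUPS}")
    return FeatureTable(ft.data.copy(), mode=ft.mode, meta=bound,
                        lineages=ft.lineages)


def collapse_taxa(ft: FeatureTable, level: str,
                  drop_unclassified: bool = False) -> FeatureTable:
    """Sum counts of all taxa sharing a lineage name at ``level``.

    Taxa unassigned at the requested rank are pooled under a single
    ``unclassified`` label (dropped when ``drop_unclassified`` is set).
    Labels duplicated across different parents are disambiguated with
    the full lineage prefix.  Per-sample totals are conserved exactly.
    """
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}; choose from {RANKS}")
    if ft.mode != "counts":
        raise ValueError("collapse_taxa requires a counts-mode table")
    if ft.lineages is None:
        raise ValueError("taxa carry no taxonomic lineages; cannot collapse")
    li = RANKS.index(level)

    names = {}
    for taxon in ft.taxa:
        lineage = ft.lineages[taxon]
        names[taxon] = lineage[li] if lineage[li] else UNCLASSIFIED

    # disambiguate identical names under different parents by full prefix
    prefix_of = {
        t: ";".join(ft.lineages[t][: li + 1]) for t in ft.taxa
    }
    by_name: dict[str, set[str]] = {}
    for t, name in names.items():
        if name != UNCLASSIFIED:
            by_name.setdefault(name, set()).add(prefix_of[t])
    labels = {}
    for t, name in names.items():
        if name != UNCLASSIFIED and len(by_name[name]) > 1:
            labels[t] = prefix_of[t]
        else:
            labels[t] = name

    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for t in ft.taxa:
        lab = labels[t]
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(t)
    if drop_unclassified:
        order = [lab for lab in order if lab != UNCLASSIFIED]

    rows = {lab: ft.data.loc[groups[lab]].sum(axis=0) for lab in order}
    data = pd.DataFrame(rows).T
    data.columns = ft.samples
    new_lineages = {}
    for lab in order:
        rep = ft.lineages[groups[lab][0]]
        trunc = rep[: li + 1] + ("",) * (len(RANKS) - li - 1)
        if lab == UNCLASSIFIED:
            trunc = ("",) * len(RANKS)
        new_lineages[lab] = trunc
    return FeatureTable(data, mode="counts", meta=ft.meta,
                        lineages=new_lineages)


def to_relative(ft: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample relative frequencies (columns sum to 1)."""
    if ft.mode != "counts":
        raise ValueError("to_relative requires a counts-mode table")
    sums = ft.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")
    data = ft.data / sums
    return FeatureTable(data, mode="relative", meta=ft.meta,
                        lineages=ft.lineages)


def merge_shared(tables: list[FeatureTable],
                 renormalize: bool = False) -> FeatureTable:
    """Merge relative-frequency tables on their shared taxa.

    Taxa are restricted to the intersection of all input taxon sets
    (sorted, so the result is independent of table order); samples are
    concatenated in input order with their dataset/group provenance.
    By default the surviving proportions are *not* renormalized, so each
    sample keeps its original scale; pass ``renormalize=True`` to rescale
    columns to sum to 1.
    """
    if not tables:
        raise ValueError("merge_shared requires at least one table")
    for ft in tables:
        if ft.mode != "relative":
            raise ValueError("merge_shared requires relative-mode tables")
        if ft.meta is None:
            raise ValueError("merge_shared requires metadata on every table "
                             "(dataset provenance)")
    shared = set(tables[0].taxa)
    for ft in tables[1:]:
        shared &= set(ft.taxa)
    if not shared:
        raise ValueError("tables share no taxa; nothing to merge")
    taxa = sorted(shared)

    all_samples: list[str] = []
    for ft in tables:
        all_samples.extend(ft.samples)
    dup = sorted({s for s in all_samples if all_samples.count(s) > 1})
    if dup:
        raise ValueError(f"colliding sample ids across tables: {dup}")

    blocks = [ft.data.loc[taxa] for ft in tables]
    data = pd.concat(blocks, axis=1)
    meta = pd.concat([ft.meta.loc[ft.samples] for ft in tables], axis=0)
    lineages = None
    if tables[0].lineages is not None:
        lineages = {t: tables[0].lineages[t] for t in taxa}
    if renormalize:
        data = data / data.sum(axis=0)
        return FeatureTable(data, mode="relative", meta=meta,
                            lineages=lineages)
    # restriction to shared taxa deliberately breaks per-sample closure
    return FeatureTable(data, mode="relative", meta=meta, lineages=lineages,
                        closed=False)
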