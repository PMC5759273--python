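"""OTU count tables, sample metadata, and table-preparation steps.

This module holds the data model shared by the whole package — a taxa-by-samples
count matrix with optional greengenes-style taxonomy, and per-sample annotations
(subject, anatomic site, sequencing batch) — together with the preparation steps
that turn a raw OTU table into an analysis-ready one: sequencing-depth summaries,
negative-control-driven contaminant removal, rarefaction to a common depth, and
aggregation of OTUs to a higher taxonomic rank.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "RANKS",
    "FormatError",
    "OtuTable",
    "SampleMetadata",
    "DepthSummary",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "summarize_depths",
    "remove_contaminant_taxa",
    "rarefy",
    "relative_abundance",
    "aggregate_by_rank",
]

SITES = ("oral", "nasal", "bronchial", "lung", "control")

#: taxonomy ranks carried in lineage strings, kingdom through genus
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class FormatError(ValueError):
    """Raised when an input file violates the table or metadata format."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {axis} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """A taxa-by-samples matrix of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids : list of str
        Unique row identifiers (OTU ids or aggregated lineage strings).
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer read counts.
    taxonomy : list of str, optional
        Per-taxon semicolon-delimited lineage, kingdom through genus.
        Greengenes-style rank prefixes (``k__`` … ``g__``) are accepted;
        an entry that is only the prefix counts as unclassified at that rank.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise FormatError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.taxon_ids):
            raise FormatError("taxonomy length does not match number of taxa")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        """Subset columns, preserving the requested order."""
        ids = list(sample_ids)
        idx = [self.sample_index(s) for s in ids]
        return OtuTable(
            list(self.taxon_ids), ids, self.counts[:, idx],
            None if self.taxonomy is None else list(self.taxonomy),
        )

    def select_taxa(self, keep: np.ndarray) -> "OtuTable":
        """Subset rows by a boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            [self.taxon_ids[i] for i in keep],
            list(self.sample_ids),
            self.counts[keep, :],
            None if self.taxonomy is None else [self.taxonomy[i] for i in keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


class SampleMetadata:
    """Per-sample annotations: subject, anatomic site, sequencing batch.

    Negative-control samples carry an empty subject id and site ``control``;
    a subject has at most one sample per site.
    """

    COLUMNS = ("sample_id", "subject_id", "site", "batch")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        for c in self.COLUMNS:
            df[c] = df[c].fillna("").astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad_site = sorted(set(df["site"]) - set(SITES))
        if bad_site:
            raise FormatError(f"unknown site value(s): {bad_site}")
        is_control = df["site"] == "control"
        if (is_control != (df["subject_id"] == "")).any():
            raise FormatError("site=control must coincide with empty subject_id")
        dup = df.loc[~is_control].duplicated(subset=["subject_id", "site"])
        if dup.any():
            row = df.loc[~is_control].loc[dup].iloc[0]
            raise FormatError(
                f"subject {row['subject_id']!r} has more than one {row['site']!r} sample"
            )
        if (df.loc[~is_control, "batch"] == "").any():
            raise FormatError("non-control samples must carry a batch label")
        self.df = df.reset_index(drop=True)

    # -- lookups ---------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def site_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "site")

    def subject_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "subject_id")

    def batch_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "batch")

    def _lookup(self, sample_id: str, col: str) -> str:
        row = self.df.loc[self.df["sample_id"] == sample_id, col]
        if row.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return row.iloc[0]

    def samples_for_site(self, site: str, within: Iterable[str] | None = None) -> list[str]:
        sel = self.df.loc[self.df["site"] == site, "sample_id"]
        if within is not None:
            allowed = set(within)
            sel = sel[sel.isin(allowed)]
        return list(sel)

    def control_ids(self) -> list[str]:
        return self.samples_for_site("control")

    def subject_sample_ids(self) -> list[str]:
        return list(self.df.loc[self.df["site"] != "control", "sample_id"])

    def sample_of(self, subject_id: str, site: str) -> str | None:
        sel = self.df.loc[
            (self.df["subject_id"] == subject_id) & (self.df["site"] == site),
            "sample_id",
        ]
        return None if sel.empty else sel.iloc[0]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class DepthSummary:
    """Total / mean / median sequencing depth over a set of samples."""

    n_samples: int
    total: int
    mean: float
    median: float
    per_sample: dict[str, int] = field(repr=False)

    def rounded(self) -> tuple[int, int, int]:
        """(total, mean, median) with mean/median rounded half away from zero,
        the convention used for display in sequencing-yield tables."""
        half_up = lambda x: int(np.floor(x + 0.5))
        return self.total, half_up(self.mean), half_up(self.median)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from TSV or BIOM-style sparse JSON.

    The TSV dialect: a header row whose first cell names the taxon-id column
    (conventionally ``#OTU ID``), one column per sample, and an optional final
    ``taxonomy`` column; subsequent rows hold integer counts.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one sample column")
        has_tax = header[-1].strip().lower() == "taxonomy"
        sample_ids = header[1 : -1 if has_tax else len(header)]
        _check_unique(sample_ids, "sample")
        taxon_ids: list[str] = []
        taxonomy: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            taxon_ids.append(cells[0])
            if has_tax:
                taxonomy.append(cells[-1])
            row = []
            for j, cell in enumerate(cells[1 : -1 if has_tax else len(cells)]):
                try:
                    value = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} in "
                        f"sample {sample_ids[j]!r}"
                    ) from None
                if value < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count in sample {sample_ids[j]!r}"
                    )
                row.append(value)
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    return OtuTable(taxon_ids, sample_ids, counts, taxonomy if has_tax else None)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        n_taxa, n_samples = doc["shape"]
        taxon_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        triplets = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM-style JSON table ({exc})") from None
    _check_unique(taxon_ids, "taxon")
    _check_unique(sample_ids, "sample")
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for i, j, v in triplets:
        if v != int(v) or v < 0:
            raise FormatError(
                f"{path}: bad count {v!r} at taxon {taxon_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        counts[i, j] = int(v)
    taxonomy = None
    if any((r.get("metadata") or {}).get("taxonomy") is not None for r in doc["rows"]):
        taxonomy = [
            (r.get("metadata") or {}).get("taxonomy") or "" for r in doc["rows"]
        ]
    return OtuTable(taxon_ids, sample_ids, counts, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            cols = ["#OTU ID"] + table.sample_ids
            if table.taxonomy is not None:
                cols.append("taxonomy")
            fh.write("\t".join(cols) + "\n")
            for i, tid in enumerate(table.taxon_ids):
                cells = [tid] + [str(v) for v in table.counts[i]]
                if table.taxonomy is not None:
                    cells.append(table.taxonomy[i])
                fh.write("\t".join(cells) + "\n")
    elif format == "biom_json":
        rows = []
        for i, tid in enumerate(table.taxon_ids):
            meta = None
            if table.taxonomy is not None:
                meta = {"taxonomy": table.taxonomy[i]}
            rows.append({"id": tid, "metadata": meta})
        nz = np.argwhere(table.counts > 0)
        doc = {
            "id": "lungbiota-otu-table",
            "format": "biom-style-json",
            "type": "OTU table",
            "matrix_type": "sparse",
            "shape": [table.n_taxa, table.n_samples],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": [[int(i), int(j), int(table.counts[i, j])] for i, j in nz],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata.read_tsv(path)


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def summarize_depths(
    table: OtuTable, metadata: SampleMetadata, include_controls: bool = False
) -> DepthSummary:
    """Per-sample column sums with total, mean and median.

    With ``include_controls=False`` (the default used for subject-level yield
    reporting), control-site samples are excluded before summing. The median of
    an even number of samples is the midpoint of the two central order
    statistics.
    """
    for s in table.sample_ids:
        metadata.site_of(s)  # raises KeyError on unknown sample
    keep = [
        s for s in table.sample_ids
        if include_controls or metadata.site_of(s) != "control"
    ]
    if not keep:
        raise ValueError("no samples after filtering")
    sub = table.select_samples(keep)
    sums = sub.column_sums()
    total = int(sums.sum())
    return DepthSummary(
        n_samples=len(keep),
        total=total,
        mean=total / len(keep),
        median=float(np.median(sums)),
        per_sample={s: int(v) for s, v in zip(keep, sums)},
    )


def remove_contaminant_taxa(
    table: OtuTable,
    metadata: SampleMetadata,
    abundance_threshold: float = 0.01,
) -> tuple[OtuTable, list[str]]:
    """Drop taxa present in negative controls *and* abundant in subject samples.

    A taxon is removed iff it has a positive count in at least one control
    sample and its pooled relative abundance across all subject (non-control)
    samples exceeds ``abundance_threshold``. With no controls in the metadata
    the table is returned unchanged. The rule is idempotent: once the offending
    taxa are gone, a second application removes nothing.
    """
    controls = [s for s in metadata.control_ids() if s in table.sample_ids]
    if not controls:
        return table, []
    subjects = [s for s in metadata.subject_sample_ids() if s in table.sample_ids]
    ctrl_idx = [table.sample_index(s) for s in controls]
    subj_idx = [table.sample_index(s) for s in subjects]
    in_controls = (table.counts[:, ctrl_idx] > 0).any(axis=1)
    subj_counts = table.counts[:, subj_idx]
    pooled_total = subj_counts.sum()
    pooled = subj_counts.sum(axis=1) / pooled_total if pooled_total > 0 else np.zeros(table.n_taxa)
    remove = in_controls & (pooled > abundance_threshold)
    removed_ids = [table.taxon_ids[i] for i in np.flatnonzero(remove)]
    return table.select_taxa(~remove), removed_ids


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stream keyed by (seed, sample id) so rarefaction is column-order independent
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode("utf-8"))])


def rarefy(
    table: OtuTable, depth: int, seed: int = 0
) -> tuple[OtuTable, list[str]]:
    """Subsample every sample without replacement to a common depth.

    Samples whose column sum falls below ``depth`` are dropped and returned in
    the ``dropped`` list. Each surviving column is a single vector
    hypergeometric draw (one rarefied data set, not an average over repeats)
    from a random stream keyed by ``(seed, sample_id)``, so the result does not
    depend on column order.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.column_sums()
    survivors = [s for s, t in zip(table.sample_ids, sums) if t >= depth]
    dropped = [s for s in table.sample_ids if s not in set(survivors)]
    if not survivors:
        raise ValueError("no samples survive rarefaction")
    sub = table.select_samples(survivors)
    out = np.empty_like(sub.counts)
    for j, sid in enumerate(survivors):
        col = sub.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            rng = _sample_rng(seed, sid)
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(list(sub.taxon_ids), survivors, out, sub.taxonomy), dropped


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Counts converted to within-sample proportions (columns sum to 1)."""
    sums = table.column_sums()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero-sum sample column: {table.sample_ids[zero[0]]!r}")
    return table.counts / sums[np.newaxis, :]


def parse_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage into cleaned rank names.

    Greengenes-style prefixes are stripped; a field that is empty or only the
    prefix yields ``""`` (unclassified at that rank). The result is padded with
    ``""`` to the six ranks kingdom..genus.
    """
    parts = [p.strip() for p in lineage.split(";")]
    out = []
    for i in range(len(RANKS)):
        cell = parts[i] if i < len(parts) else ""
        for pref in _RANK_PREFIXES:
            if cell.startswith(pref):
                cell = cell[len(pref):]
                break
        out.append(cell.strip())
    return out


def aggregate_by_rank(
    table: OtuTable, rank: str
) -> tuple[OtuTable, int]:
    """Sum OTUs sharing a lineage prefix through ``rank``; drop unclassified ones.

    Returns the aggregated table (taxon ids are the truncated lineage strings,
    in order of first appearance) and the number of dropped OTUs. Reads are
    conserved: the output grand total equals the input total minus the reads of
    dropped taxa.
    """
    if table.taxonomy is None:
        raise ValueError("taxonomy is required for rank aggregation")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    depth_idx = RANKS.index(rank)
    groups: dict[tuple[str, ...], list[int]] = {}
    n_dropped = 0
    order: list[tuple[str, ...]] = []
    for i, lin in enumerate(table.taxonomy):
        levels = parse_lineage(lin)
        if levels[depth_idx] == "":
            n_dropped += 1
            continue
        key = tuple(levels[: depth_idx + 1])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    taxon_ids = []
    taxonomy = []
    rows = np.zeros((len(order), table.n_samples), dtype=np.int64)
    for r, key in enumerate(order):
        lineage = ";".join(
            pref + name for pref, name in zip(_RANK_PREFIXES, key)
        )
        taxon_ids.append(lineage)
        taxonomy.append(lineage)
        rows[r] = table.counts[groups[key], :].sum(axis=0)
    return OtuTable(taxon_ids, list(table.sample_ids), rows, taxonomy), n_dropped
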