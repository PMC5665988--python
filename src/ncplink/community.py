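"""OTU count-table container, I/O and normalization.

The unit of analysis is the OTU (18S amplicons clustered at 97% identity).
Tables are stored samples x OTUs in memory; on disk the QIIME "classic"
tab-separated dialect is used (rows = OTUs, first column the OTU id,
optional trailing taxonomy column with a semicolon-delimited lineage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "AbundanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "filter_rare",
    "standardize_depth",
    "relative_abundance",
    "aggregate_taxa",
    "top_k_otus",
]

#: column headers recognised as the taxonomy column (case-insensitive)
_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage", "consensuslineage", "lineage"}


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with ids and optional taxonomy.

    ``counts`` may be real-valued after depth standardization; raw tables
    hold nonnegative integers.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs matrix")
        n, p = self.counts.shape
        if n != len(self.sample_ids) or p != len(self.otu_ids):
            raise ValueError(
                f"shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != p:
            raise ValueError("duplicate OTU ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.counts[:, idx], list(self.sample_ids), list(otu_ids), tax)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class AbundanceMatrix:
    """Relative abundances in percent of reads per sample (rows sum to 100)."""

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


def read_otu_table(path) -> OtuTable:
    """Read a QIIME-classic TSV OTU table (rows = OTUs, columns = samples).

    Lines starting with ``#`` before the header are skipped, except the
    header row itself which conventionally begins ``#OTU ID``. A trailing
    taxonomy column is detected by name.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#") and not line.lower().startswith("#otu"):
            continue
        header_idx = i
        break
    if header_idx is None:
        raise ValueError(f"{path}: no header line found")
    header = lines[header_idx].lstrip("#").split("\t")
    header[0] = header[0].strip()
    ncol = len(header)
    tax_col = ncol - 1 if header[-1].strip().lower() in _TAXONOMY_HEADERS else None

    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol} fields, got {len(parts)}"
            )
        otu = parts[0].strip()
        stop = tax_col if tax_col is not None else ncol
        try:
            vals = [float(v) for v in parts[1:stop]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric count ({exc})") from None
        if any(v < 0 for v in vals):
            raise ValueError(f"{path}:{lineno}: negative count for OTU {otu}")
        if otu in taxonomy or otu in otu_ids:
            raise ValueError(f"{path}:{lineno}: duplicate OTU id {otu}")
        otu_ids.append(otu)
        rows.append(vals)
        if tax_col is not None:
            taxonomy[otu] = parts[tax_col].strip()

    sample_ids = [h.strip() for h in header[1:tax_col if tax_col else ncol]]
    counts = np.array(rows, dtype=float).T  # -> samples x OTUs
    if counts.size == 0:
        counts = counts.reshape(len(sample_ids), 0)
    return OtuTable(counts, sample_ids, otu_ids, taxonomy or None)


def write_otu_table(table: OtuTable, path) -> None:
    """Write in the same QIIME-classic dialect accepted by :func:`read_otu_table`."""
    with open(path, "w") as fh:
        cols = ["#OTU ID"] + table.sample_ids
        if table.taxonomy is not None:
            cols.append("taxonomy")
        fh.write("\t".join(cols) + "\n")
        mat = table.counts
        integral = np.allclose(mat, np.round(mat))
        for j, otu in enumerate(table.otu_ids):
            vals = mat[:, j]
            if integral:
                fields = [str(int(round(v))) for v in vals]
            else:
                fields = [format(v, ".10g") for v in vals]
            row = [otu] + fields
            if table.taxonomy is not None:
                row.append(table.taxonomy.get(otu, ""))
            fh.write("\t".join(row) + "\n")


def filter_rare(table: OtuTable, min_count: int = 3,
                min_prevalence: float = 0.2) -> OtuTable:
    """Prevalence filter: keep OTUs with >= min_count reads in >= min_prevalence of samples.

    The boundary is inclusive (an OTU present at exactly the required
    prevalence is kept). OTU order is preserved.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prev = (table.counts >= min_count).mean(axis=0)
    keep = prev >= min_prevalence
    if not keep.any():
        warnings.warn("rare-taxa filter removed every OTU", stacklevel=2)
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    tax = None
    if table.taxonomy is not None:
        tax = {o: table.taxonomy[o] for o in kept_ids if o in table.taxonomy}
    return OtuTable(table.counts[:, keep], list(table.sample_ids), kept_ids, tax)


def standardize_depth(table: OtuTable) -> OtuTable:
    """Scale every sample to the median sequencing depth.

    Within-sample proportions are preserved exactly; the returned counts are
    real-valued with row sums all equal to the median of the original totals.
    """
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {', '.join(bad)}")
    median = float(np.median(totals))
    scaled = table.counts * (median / totals)[:, None]
    return OtuTable(scaled, list(table.sample_ids), list(table.otu_ids),
                    dict(table.taxonomy) if table.taxonomy else None)


def relative_abundance(table: OtuTable) -> AbundanceMatrix:
    """Percent of reads per sample; rows sum to 100."""
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {', '.join(bad)}")
    values = 100.0 * table.counts / totals[:, None]
    return AbundanceMatrix(values, list(table.sample_ids), list(table.otu_ids))


def _group_of(lineage: str, level: int) -> str:
    fields = [f.strip() for f in lineage.split(";") if f.strip()]
    if not fields:
        return "others"
    return ";".join(fields[:level])


def aggregate_taxa(table: OtuTable, level: int | None = None,
                   mapping: dict[str, str] | None = None,
                   pool_below_pct: float | None = None) -> OtuTable:
    """Sum counts within taxonomic groups.

    Groups come either from truncating the semicolon-delimited lineage at
    ``level`` ranks, or from an explicit OTU -> group ``mapping``. OTUs with
    no group end up in ``"others"``. If ``pool_below_pct`` is given, groups
    holding less than that percentage of total reads are also pooled into
    ``"others"`` afterwards (the convention used when plotting community
    composition).
    """
    if mapping is None:
        if table.taxonomy is None:
            raise ValueError("table has no taxonomy and no mapping was supplied")
        if level is None:
            raise ValueError("supply a lineage level or an explicit mapping")
        mapping = {o: _group_of(table.taxonomy.get(o, ""), level)
                   for o in table.otu_ids}
    groups: list[str] = []
    for otu in table.otu_ids:
        groups.append(mapping.get(otu, "others"))
    names = sorted(set(groups))
    mat = np.zeros((table.n_samples, len(names)))
    col = {g: i for i, g in enumerate(names)}
    for j, g in enumerate(groups):
        mat[:, col[g]] += table.counts[:, j]

    if pool_below_pct is not None:
        grand = mat.sum()
        share = 100.0 * mat.sum(axis=0) / grand
        minor = [g for g, s in zip(names, share) if s < pool_below_pct and g != "others"]
        if minor:
            keep = [g for g in names if g not in minor]
            if "others" not in keep:
                keep.append("others")
            new = np.zeros((table.n_samples, len(keep)))
            kcol = {g: i for i, g in enumerate(keep)}
            for g in names:
                target = "others" if g in minor else g
                new[:, kcol[target]] += mat[:, col[g]]
            names, mat = keep, new

    return OtuTable(mat, list(table.sample_ids), names, None)


def top_k_otus(table: OtuTable, k: int = 20) -> list[str]:
    """The k most dominant OTUs by total reads, ties broken lexicographically."""
    if k > table.n_otus:
        raise ValueError(f"k={k} exceeds number of OTUs ({table.n_otus})")
    totals = table.otu_totals()
    order = sorted(range(table.n_otus), key=lambda j: (-totals[j], table.otu_ids[j]))
    return [table.otu_ids[j] for j in order[:k]]
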