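"""Count-matrix container, I/O, normalization, and mean-based gene filtering.

The universal input for this package is a genes-by-samples table of
non-negative values (raw read counts or reads-per-million) together with a
sample -> group assignment.  Values are kept as floats: operations that
require integer counts (the Poisson branches) validate integrality
themselves.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "FilterConfig",
    "read_count_table",
    "read_group_map",
    "normalize_cpm",
    "filter_by_mean",
    "write_results_table",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative values with group labels.

    Parameters
    ----------
    data:
        DataFrame indexed by gene ID with one column per sample ID.
    group_labels:
        Mapping sample ID -> group name.  Every sample must be assigned;
        downstream two-group operations additionally require exactly two
        distinct groups.
    """

    data: pd.DataFrame
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_labels:
            self.group_labels = {s: "all" for s in self.data.columns}
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            gene, sample = self._locate(np.isnan(values))
            raise ValueError(f"non-numeric value at gene {gene!r}, sample {sample!r}")
        if (values < 0).any():
            gene, sample = self._locate(values < 0)
            raise ValueError(f"negative value at gene {gene!r}, sample {sample!r}")
        missing = [s for s in self.data.columns if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        unknown = [s for s in self.group_labels if s not in self.data.columns]
        if unknown:
            raise ValueError(f"group map names samples absent from the table: {unknown}")

    def _locate(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.data.index[i]), str(self.data.columns[j])

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def groups(self) -> list[str]:
        """Distinct group names in order of first appearance over samples."""
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.group_labels[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.data.columns if self.group_labels[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to the samples of one group."""
        return self.data[self.samples_in_group(group)]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FilterConfig:
    """Mean-read filter: keep genes with mean reads above ``mean_threshold``.

    ``per_group=True`` requires the threshold to be exceeded in every group
    separately; otherwise the mean is pooled over all samples.
    """

    mean_threshold: float = 10.0
    per_group: bool = False

    def __post_init__(self) -> None:
        if self.mean_threshold < 0:
            raise ValueError("mean_threshold must be >= 0")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV with no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"group map {path} must have exactly 2 columns")
    return dict(zip(df[0], df[1]))


def read_count_table(
    path: str | Path,
    fmt: str | None = None,
    group_map: Mapping[str, str] | str | Path | None = None,
) -> CountMatrix:
    """Read a genes-in-rows count table (first column gene IDs, header samples).

    ``fmt`` is ``"tsv"`` or ``"csv"``; when omitted it is inferred from the
    file suffix (default tsv).  ``group_map`` is a mapping or the path of a
    two-column sidecar TSV.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[fmt]
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if isinstance(group_map, (str, Path)):
        group_map = read_group_map(group_map)
    labels = dict(group_map) if group_map is not None else {}
    return CountMatrix(df, labels)


def normalize_cpm(m: CountMatrix) -> CountMatrix:
    """Scale every sample (column) to a total of 10^6 (counts per million)."""
    sums = m.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero) > 0:
        raise ValueError(f"cannot CPM-normalize all-zero sample {zero.index[0]!r}")
    scaled = m.data / sums * 1e6
    return CountMatrix(scaled, dict(m.group_labels))


def filter_by_mean(m: CountMatrix, cfg: FilterConfig | None = None) -> CountMatrix:
    """Keep genes whose mean reads exceed ``cfg.mean_threshold`` (strictly).

    High-read genes are conventionally defined as mean reads > 10, which is
    the default threshold.
    """
    cfg = cfg or FilterConfig()
    if cfg.per_group:
        keep = pd.Series(True, index=m.data.index)
        for g in m.groups:
            keep &= m.group_values(g).mean(axis=1) > cfg.mean_threshold
    else:
        keep = m.data.mean(axis=1) > cfg.mean_threshold
    kept = int(keep.sum())
    logger.info(
        "filter_by_mean(threshold=%g, per_group=%s): kept %d of %d genes",
        cfg.mean_threshold, cfg.per_group, kept, m.n_genes,
    )
    if kept == 0:
        logger.warning("filter_by_mean removed every gene")
    return CountMatrix(m.data.loc[keep], dict(m.group_labels))


def results_frame(rows: Iterable) -> pd.DataFrame:
    """Convert homogeneous result records (dataclasses or dicts) to a frame.

    Column order follows the dataclass field order (or dict insertion
    order of the first record); missing values become NaN.
    """
    rows = list(rows)
    if not rows:
        return pd.DataFrame()
    first = rows[0]
    if dataclasses.is_dataclass(first):
        columns = [f.name for f in dataclasses.fields(first)]
        records = [dataclasses.asdict(r) for r in rows]
    else:
        columns = list(first.keys())
        records = [dict(r) for r in rows]
    return pd.DataFrame.from_records(records, columns=columns)


def write_results_table(
    rows: Iterable | pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write result records as TSV with a header row; missing values as "NA".

    ``header_lines`` are emitted first as '#'-prefixed comment lines
    (tool version, seed, configuration).
    """
    df = rows if isinstance(rows, pd.DataFrame) else results_frame(rows)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
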