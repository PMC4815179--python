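"""Count-matrix and result-table I/O for axial-zone RNA-seq.

The central container is :class:`ZoneCountTable`: raw integer counts for
transcripts across ordered anterior-to-posterior body zones, together with
per-zone library sizes.  Counts are read from tab-separated tables or
Matrix Market triplet files (with sidecar row/column name files); results
are written back as TSV.

Zone order is axial order and is never re-sorted.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "ZoneCountTable",
    "RunConfig",
    "read_counts",
    "write_counts",
    "write_results",
    "read_config",
    "write_config",
]

#: literal header of the first TSV column
ID_COLUMN = "transcript_id"


class CountsParseError(ValueError):
    """Malformed counts file (bad header, bad value, duplicate ids)."""


@dataclasses.dataclass
class ZoneCountTable:
    """Raw integer counts for transcripts across ordered axial zones.

    Parameters
    ----------
    transcript_ids
        Unique transcript identifiers, row order of ``counts``.
    zone_labels
        Unique zone names in axial order, anterior first (default "1".."6").
    counts
        Non-negative integer matrix, transcripts x zones.
    library_sizes
        Positive per-zone sequencing depth.  Defaults to the column sums of
        ``counts``; the study's own library sizes came from full alignments,
        so an override is accepted.
    """

    transcript_ids: list[str]
    zone_labels: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (transcripts x zones)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)[0]
                raise CountsParseError(
                    f"non-integer count for transcript "
                    f"{self.transcript_ids[bad[0]]!r}, zone {self.zone_labels[bad[1]]!r}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            g, z = np.argwhere(self.counts < 0)[0]
            raise CountsParseError(
                f"negative count for transcript {self.transcript_ids[g]!r}, "
                f"zone {self.zone_labels[z]!r}"
            )
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.zone_labels = [str(z) for z in self.zone_labels]
        n_g, n_z = self.counts.shape
        if len(self.transcript_ids) != n_g:
            raise ValueError("transcript_ids length does not match counts rows")
        if len(self.zone_labels) != n_z:
            raise ValueError("zone_labels length does not match counts columns")
        if len(set(self.transcript_ids)) != n_g:
            seen: set[str] = set()
            dup = next(t for t in self.transcript_ids if t in seen or seen.add(t))
            raise CountsParseError(f"duplicate transcript id {dup!r}")
        if len(set(self.zone_labels)) != n_z:
            raise CountsParseError("duplicate zone labels")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if len(self.library_sizes) != n_z:
            raise ValueError("library_sizes length does not match zone count")
        if (self.library_sizes <= 0).any():
            z = int(np.argwhere(self.library_sizes <= 0)[0][0])
            raise ValueError(
                f"library size must be positive; zone {self.zone_labels[z]!r} "
                f"has {self.library_sizes[z]}"
            )

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_zones(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by transcript, columns in axial order."""
        return pd.DataFrame(
            self.counts, index=self.transcript_ids, columns=self.zone_labels
        )

    def subset(self, keep: np.ndarray) -> "ZoneCountTable":
        """Row subset (boolean mask or integer index), keeping library sizes."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ZoneCountTable(
            transcript_ids=[self.transcript_ids[i] for i in keep],
            zone_labels=list(self.zone_labels),
            counts=self.counts[keep],
            library_sizes=self.library_sizes.copy(),
        )


@dataclasses.dataclass
class RunConfig:
    """Analysis parameters for the zone-specificity pipeline.

    ``cpm_cutoff`` is the low-expression filter threshold in counts per
    million; a transcript is dropped only when below the cutoff in every
    zone.  ``dispersion`` is the negative-binomial overdispersion phi
    (variance = mu + phi*mu^2) assumed by the exact test; the pooled
    one-library-per-zone design leaves it inestimable, so it is explicit.
    ``prior_cpm`` is the pseudo-CPM added to both sides of the log2
    fold-change so it stays finite.
    """

    cpm_cutoff: float = 0.5
    alpha: float = 0.05
    dispersion: float = 0.1
    dispersion_mode: str = "fixed"
    prior_cpm: float = 0.5
    trim_m: float = 0.3
    trim_a: float = 0.05
    seed: int = 0
    library_sizes: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_m < 0.5:
            raise ValueError("trim_m must be in [0, 0.5)")
        if not 0.0 <= self.trim_a < 0.5:
            raise ValueError("trim_a must be in [0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.cpm_cutoff < 0:
            raise ValueError("cpm_cutoff must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.prior_cpm <= 0:
            raise ValueError("prior_cpm must be > 0")
        if self.dispersion_mode not in ("fixed", "poisson"):
            raise ValueError("dispersion_mode must be 'fixed' or 'poisson'")

    @property
    def effective_dispersion(self) -> float:
        return 0.0 if self.dispersion_mode == "poisson" else self.dispersion


def read_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def _read_counts_tsv(path: Path, library_sizes: Sequence[int] | None) -> ZoneCountTable:
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i + 1, ln.rstrip("\n"))
            for i, ln in enumerate(fh)
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise CountsParseError(f"{path}: empty counts file")
    header_no, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2 or cols[0] != ID_COLUMN:
        raise CountsParseError(
            f"{path}:{header_no}: header must start with {ID_COLUMN!r} "
            f"followed by zone labels; got {header!r}"
        )
    zone_labels = cols[1:]
    ids: list[str] = []
    rows: list[list[int]] = []
    for line_no, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise CountsParseError(
                f"{path}:{line_no}: expected {len(cols)} fields, got {len(fields)}"
            )
        ids.append(fields[0])
        row = []
        for z, raw in zip(zone_labels, fields[1:]):
            try:
                value = int(raw)
            except ValueError:
                raise CountsParseError(
                    f"{path}:{line_no}: non-integer count {raw!r} for "
                    f"transcript {fields[0]!r}, zone {z!r}"
                ) from None
            if value < 0:
                raise CountsParseError(
                    f"{path}:{line_no}: negative count {value} for "
                    f"transcript {fields[0]!r}, zone {z!r}"
                )
            row.append(value)
        rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(zone_labels))
    return ZoneCountTable(ids, zone_labels, counts, library_sizes)


def _read_counts_mtx(path: Path, library_sizes: Sequence[int] | None) -> ZoneCountTable:
    # triplet MTX plus sidecar <stem>.rows / <stem>.cols name files
    rows_path = path.with_suffix(".rows")
    cols_path = path.with_suffix(".cols")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise FileNotFoundError(f"missing sidecar name file {side}")
    mat = scipy.io.mmread(str(path))
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    ids = rows_path.read_text(encoding="utf-8").split()
    zones = cols_path.read_text(encoding="utf-8").split()
    return ZoneCountTable(ids, zones, dense, library_sizes)


def read_counts(
    path: str | Path,
    format: str | None = None,
    library_sizes: Sequence[int] | None = None,
) -> ZoneCountTable:
    """Read a counts matrix from TSV or Matrix Market triplet format.

    TSV files are UTF-8, tab-separated, with ``#``-prefixed comment lines
    ignored, a header row of zone labels and a first column literally named
    ``transcript_id``.  MTX files must be accompanied by ``.rows`` /
    ``.cols`` sidecar files listing transcript and zone names.  Column
    order is preserved as axial order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx-triplet" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        return _read_counts_tsv(path, library_sizes)
    if format == "mtx-triplet":
        return _read_counts_mtx(path, library_sizes)
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(table: ZoneCountTable, path: str | Path) -> None:
    """Write counts as the TSV dialect read back by :func:`read_counts`."""
    path = Path(path)
    buf = _stdio.StringIO()
    buf.write(ID_COLUMN + "\t" + "\t".join(table.zone_labels) + "\n")
    for tid, row in zip(table.transcript_ids, table.counts):
        buf.write(tid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-transcript results table as TSV.

    ``results`` carries one row per transcript in input order: per-zone
    normalized CPM columns (``cpm_<zone>``), per-zone BH-adjusted q-values
    (``q_<zone>``), and the composite membership ``code`` ("none" when the
    transcript is specific to no zone).  Floats are written with 12
    significant digits so a re-read reproduces them.
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    out = results.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "code": str})
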