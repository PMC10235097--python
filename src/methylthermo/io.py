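"""Reading, validating, filtering and aligning per-cytosine count tables.

The raw observable of a bisulfite-sequencing methylome is, per cytosine
site, the number of reads calling the base methylated (``n_meth``) and
unmethylated (``n_unmeth``).  Samples are held as a
:class:`MethylomeSample`, a thin wrapper around a pandas DataFrame keyed
by (chromosome, position, strand).  Counts are authoritative; the
percentage column of a Bismark coverage file is used for validation only.

Coordinates are 1-based inclusive (Bismark convention).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError, ParseError

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["chromosome", "position", "strand"]
SITE_COLUMNS = KEY_COLUMNS + ["context", "n_meth", "n_unmeth"]

#: tolerance (percentage points) for the Bismark percentage-column check
PERCENT_TOLERANCE = 0.5

Strand = Literal["+", "-", "unknown"]
Context = Literal["CG", "CHG", "CHH", "other"]


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine with its methylated/unmethylated read counts."""

    chromosome: str
    position: int
    strand: Strand = "unknown"
    context: Context = "other"
    n_meth: int = 0
    n_unmeth: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


class MethylomeSample:
    """A keyed collection of cytosine sites for one sample.

    Parameters
    ----------
    sample_id:
        Identifier of the sample.
    sites:
        DataFrame with columns ``chromosome, position, strand, context,
        n_meth, n_unmeth`` or an iterable of :class:`CytosineSite`.
    group_label:
        Experimental group (e.g. ``control`` / ``treatment``).
    """

    def __init__(
        self,
        sample_id: str,
        sites: pd.DataFrame | Iterable[CytosineSite],
        group_label: str = "",
    ) -> None:
        if not isinstance(sites, pd.DataFrame):
            sites = pd.DataFrame(
                [
                    (s.chromosome, s.position, s.strand, s.context, s.n_meth, s.n_unmeth)
                    for s in sites
                ],
                columns=SITE_COLUMNS,
            )
        missing = [c for c in SITE_COLUMNS if c not in sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns {missing}")
        df = sites.loc[:, SITE_COLUMNS].copy()
        df["chromosome"] = df["chromosome"].astype(str)
        df["position"] = df["position"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
        if (df["position"] < 1).any():
            raise ValueError("positions must be >= 1")
        if (df[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise DuplicateRecordError(
                f"sample {sample_id!r}: duplicate site key {tuple(first)}"
            )
        self.sample_id = sample_id
        self.group_label = group_label
        self._df = df.reset_index(drop=True)

    @property
    def sites(self) -> pd.DataFrame:
        """Site table (copy-free view; treat as read-only)."""
        return self._df

    @property
    def coverage(self) -> pd.Series:
        return self._df["n_meth"] + self._df["n_unmeth"]

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[CytosineSite]:
        for row in self._df.itertuples(index=False):
            yield CytosineSite(
                row.chromosome, row.position, row.strand, row.context,
                row.n_meth, row.n_unmeth,
            )

    def keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self._df[KEY_COLUMNS])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MethylomeSample({self.sample_id!r}, {len(self)} sites, "
            f"group={self.group_label!r})"
        )


@dataclass
class SiteMatrix:
    """Counts of several samples aligned on their common site keys.

    ``counts`` is indexed by (chromosome, position, strand) with a column
    MultiIndex (sample_id, {n_meth, n_unmeth}); intersection semantics —
    every cell is present.
    """

    counts: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def sample_counts(self, sample_id: str) -> pd.DataFrame:
        return self.counts[sample_id]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cytosine_table(
    path: str | Path,
    format: str = "bismark_cov",
    sample_id: str | None = None,
    group_label: str = "",
    column_map: dict[str, int] | None = None,
) -> MethylomeSample:
    """Read a per-cytosine count table.

    ``bismark_cov`` expects the six Bismark coverage columns
    ``chrom  start  end  methylation%  count_methylated  count_unmethylated``
    (1-based inclusive).  ``tsv`` expects a generic tab-separated file whose
    0-based column indices are declared in ``column_map`` with keys
    ``chromosome, position, n_meth, n_unmeth`` and optionally
    ``strand, context``.

    The percentage column of a coverage file is validated against the
    counts (tolerance 0.5 percentage points) and discrepancies are logged;
    counts are kept as ground truth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("bismark_cov", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]

    if format == "tsv" and column_map is None:
        column_map = {"chromosome": 0, "position": 1, "n_meth": 2, "n_unmeth": 3}

    records: list[tuple] = []
    n_percent_mismatch = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bismark_cov":
                    if len(fields) != 6:
                        raise ValueError(f"expected 6 columns, got {len(fields)}")
                    chrom, start, _end, pct, n_meth, n_unmeth = fields
                    position = int(start)
                    meth, unmeth = int(n_meth), int(n_unmeth)
                    strand, context = "unknown", "other"
                    total = meth + unmeth
                    if total > 0:
                        observed = 100.0 * meth / total
                        if abs(observed - float(pct)) > PERCENT_TOLERANCE:
                            n_percent_mismatch += 1
                else:
                    assert column_map is not None
                    chrom = fields[column_map["chromosome"]]
                    position = int(fields[column_map["position"]])
                    meth = int(fields[column_map["n_meth"]])
                    unmeth = int(fields[column_map["n_unmeth"]])
                    strand = (
                        fields[column_map["strand"]] if "strand" in column_map else "unknown"
                    )
                    context = (
                        fields[column_map["context"]] if "context" in column_map else "other"
                    )
                if position < 1:
                    raise ValueError(f"position {position} < 1")
                if meth < 0 or unmeth < 0:
                    raise ValueError("negative count")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
            records.append((chrom, position, strand, context, meth, unmeth))

    if n_percent_mismatch:
        logger.warning(
            "%s: %d line(s) with methylation %% inconsistent with counts "
            "(> %.1f points); counts kept as ground truth",
            path.name, n_percent_mismatch, PERCENT_TOLERANCE,
        )
    df = pd.DataFrame(records, columns=SITE_COLUMNS)
    return MethylomeSample(sample_id, df, group_label=group_label)


def write_cytosine_table(
    sample: MethylomeSample, path: str | Path, format: str = "bismark_cov"
) -> None:
    """Write a sample back to disk, bit-exact on integer columns.

    ``bismark_cov`` emits the six coverage columns (strand/context are not
    part of that dialect and are dropped); ``tsv`` emits all site columns
    with a header.
    """
    path = Path(path)
    df = sample.sites
    if format == "bismark_cov":
        total = (df["n_meth"] + df["n_unmeth"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * df["n_meth"].to_numpy() / total, 0.0)
        out = pd.DataFrame(
            {
                "chrom": df["chromosome"],
                "start": df["position"],
                "end": df["position"],
                "pct": np.round(pct, 6),
                "n_meth": df["n_meth"],
                "n_unmeth": df["n_unmeth"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    elif format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_sites(
    sample: MethylomeSample,
    min_total_reads: int = 4,
    max_total_reads: int = 500,
) -> MethylomeSample:
    """Keep sites whose total coverage lies in [min_total_reads, max_total_reads].

    The default ceiling of 500 reads controls PCR bias; the floor of 4
    reads is a conservative noise floor for level estimation.  Returns a
    new sample; order is preserved and an empty result is legal.
    """
    if not (0 <= min_total_reads <= max_total_reads):
        raise ValueError("need 0 <= min_total_reads <= max_total_reads")
    cov = sample.coverage
    keep = (cov >= min_total_reads) & (cov <= max_total_reads)
    return MethylomeSample(
        sample.sample_id, sample.sites.loc[keep], group_label=sample.group_label
    )


def merge_cpg_strands(sample: MethylomeSample) -> MethylomeSample:
    """Optionally sum the counts of the two strands of each CpG pair.

    A CpG on the minus strand at position p pairs with the plus strand at
    p−1; merged sites are reported on the plus strand.  Off by default in
    every pipeline; exposed for symmetric-CpG analyses.
    """
    df = sample.sites.copy()
    pair_pos = np.where(df["strand"] == "-", df["position"] - 1, df["position"])
    df["position"] = pair_pos
    merged = (
        df.groupby(["chromosome", "position"], sort=False, as_index=False)
        .agg(n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
    )
    merged["strand"] = "+"
    merged["context"] = "CG"
    return MethylomeSample(
        sample.sample_id, merged[SITE_COLUMNS], group_label=sample.group_label
    )


def align_samples(samples: Sequence[MethylomeSample]) -> SiteMatrix:
    """Align ≥ 2 samples on the intersection of their site keys.

    The result is independent of sample order up to column order.  An
    empty intersection yields an empty matrix with an explicit warning.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to align")
    ids: list[str] = []
    for s in samples:  # repeated ids get a positional suffix
        sid = s.sample_id
        if sid in ids:
            k = 2
            while f"{sid}#{k}" in ids:
                k += 1
            sid = f"{sid}#{k}"
        ids.append(sid)
    frames = []
    for sid, s in zip(ids, samples):
        f = s.sites.set_index(KEY_COLUMNS)[["n_meth", "n_unmeth"]]
        f.columns = pd.MultiIndex.from_product([[sid], f.columns])
        frames.append(f)
    joined = frames[0]
    for f in frames[1:]:
        joined = joined.join(f, how="inner")
    joined = joined.sort_index()
    if joined.empty:
        warnings.warn(
            "align_samples: empty site intersection across "
            f"{[s.sample_id for s in samples]}",
            stacklevel=2,
        )
    return SiteMatrix(counts=joined, sample_ids=ids)
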