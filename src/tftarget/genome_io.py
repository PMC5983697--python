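"""Readers, writers and domain containers for every external format the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
GTF (1-based, inclusive) is converted on read and back on write.  Expression
matrices carry an explicit ``scale`` tag (``linear`` or ``log2p1``) so every
downstream operation can state, and obtain, the scale it needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "Peak",
    "ExpressionMatrix",
    "ClinicalTable",
    "GenomeIOError",
    "read_gene_models",
    "write_gene_models",
    "read_peaks",
    "write_peaks",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
]

VALID_STRANDS = frozenset("+-")
# extracted text sometimes carries a unicode minus; accept it as '-'
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


class GenomeIOError(ValueError):
    """Malformed input file or invariant violation during I/O."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand and its derived transcription start site (TSS).

    Coordinates are 0-based half-open.  The TSS is the first transcribed base:
    ``start`` on the + strand, ``end - 1`` on the - strand.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise GenomeIOError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq interval (0-based half-open) with an optional summit offset."""

    chrom: str
    start: int
    end: int
    name: str = "."
    signal: float = 0.0
    summit_offset: int | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"peak {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.signal < 0:
            raise GenomeIOError(f"peak {self.name!r}: negative signal {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise GenomeIOError(
                f"peak {self.name!r}: summit offset {self.summit_offset} outside interval"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a declared scale.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``scale`` is ``"linear"`` (nonnegative) or ``"log2p1"`` (values are
    log2(x + 1) of linear expression).
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2p1"):
            raise GenomeIOError(f"unknown expression scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise GenomeIOError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise GenomeIOError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise GenomeIOError("expression matrix contains non-finite values")
        if self.scale == "linear" and (arr < 0).any():
            raise GenomeIOError("negative values in a linear-scale expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values) - 1.0, scale="linear")

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == "log2p1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2p1")


@dataclass
class ClinicalTable:
    """Per-sample overall-survival records: time in days and a death indicator."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample", "time", "event"]))

    def __post_init__(self) -> None:
        required = ["sample", "time", "event"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise GenomeIOError(f"clinical table missing columns: {missing}")
        df = self.data[required].copy()
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise GenomeIOError(f"duplicate clinical sample ids: {dups}")
        if len(df) and not (df["time"] > 0).all():
            bad = df.loc[~(df["time"] > 0), "sample"].tolist()
            raise GenomeIOError(f"non-positive survival times for samples: {bad}")
        if len(df) and not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "sample"].tolist()
            raise GenomeIOError(f"event indicator not in {{0,1}} for samples: {bad}")
        df["event"] = df["event"].astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample"])


# ---------------------------------------------------------------------------
# gene models

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_line(line: str, lineno: int) -> GeneModel | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9:
        raise GenomeIOError(f"line {lineno}: expected 9 tab-separated GTF fields, got {len(fields)}")
    chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
    if feature != "gene":
        return None
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError:
        raise GenomeIOError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
    strand = _STRAND_ALIASES.get(strand)
    if strand is None:
        raise GenomeIOError(f"line {lineno}: missing or invalid strand")
    attr = dict(_GTF_ATTR_RE.findall(attrs))
    if "gene_id" not in attr:
        raise GenomeIOError(f"line {lineno}: no gene_id attribute")
    # GTF is 1-based inclusive; internal is 0-based half-open
    return GeneModel(
        gene_id=attr["gene_id"],
        symbol=attr.get("gene_name", attr["gene_id"]),
        chrom=chrom,
        strand=strand,
        start=start1 - 1,
        end=end1,
    )


def read_gene_models(path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from a GTF (gene-feature rows) or a TSS BED6 file.

    Raises :class:`GenomeIOError` on malformed lines (with the line number),
    a missing strand, or a duplicated gene_id.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if format == "gtf":
                gene = _parse_gtf_line(line, lineno)
                if gene is None:
                    continue
            elif format == "tss-bed":
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise GenomeIOError(f"line {lineno}: TSS BED needs 6 columns")
                chrom, start_s, end_s, name, _score, strand = fields[:6]
                strand = _STRAND_ALIASES.get(strand)
                if strand is None:
                    raise GenomeIOError(f"line {lineno}: missing or invalid strand")
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise GenomeIOError(f"line {lineno}: non-integer coordinates") from None
                gene = GeneModel(gene_id=name, symbol=name, chrom=chrom, strand=strand, start=start, end=end)
            else:
                raise GenomeIOError(f"unknown gene-model format {format!r}")
            if gene.gene_id in seen:
                raise GenomeIOError(f"line {lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_models(genes, path) -> None:
    """Write gene models as Ensembl-dialect GTF gene rows (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path, format: str = "narrowPeak", source_label: str = "") -> list[Peak]:
    """Read peaks from BED3+ or ENCODE 10-column narrowPeak.

    narrowPeak column 10 (point source) becomes ``summit_offset``; the sentinel
    value -1 maps to absent.  Coordinates stay 0-based half-open as in BED.
    """
    peaks: list[Peak] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if format == "narrowPeak" and len(fields) < 10:
                raise GenomeIOError(f"line {lineno}: narrowPeak needs 10 columns, got {len(fields)}")
            if format == "bed" and len(fields) < 3:
                raise GenomeIOError(f"line {lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomeIOError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise GenomeIOError(f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            signal = 0.0
            summit: int | None = None
            if format == "narrowPeak":
                try:
                    signal = float(fields[6])
                    point_source = int(fields[9])
                except ValueError:
                    raise GenomeIOError(f"line {lineno}: bad signal/point-source column") from None
                summit = None if point_source == -1 else point_source
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=name,
                    signal=signal,
                    summit_offset=summit,
                    source_label=source_label,
                )
            )
    return peaks


def write_peaks(peaks, path, format: str = "narrowPeak") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for p in peaks:
            if format == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t{p.signal:g}\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")


# ---------------------------------------------------------------------------
# expression / clinical tables


def read_expression(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        raise GenomeIOError(f"duplicate gene ids in {path}")
    def _parse(col: pd.Series) -> pd.Series:
        # float(str) is the exact inverse of repr-based writing; NA/garbage -> NaN
        def one(v):
            try:
                return float(v)
            except ValueError:
                return float("nan")

        return col.map(one)

    numeric = df.apply(_parse)
    bad = numeric.isna()
    if bad.to_numpy().any():
        gene = numeric.index[bad.any(axis=1)][0]
        sample = numeric.columns[bad.loc[gene]][0]
        raise GenomeIOError(f"non-numeric or missing cell at gene {gene!r}, sample {sample!r}")
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    try:
        df["time"] = pd.to_numeric(df["time"], errors="raise")
        df["event"] = pd.to_numeric(df["event"], errors="raise")
    except (ValueError, KeyError) as exc:
        raise GenomeIOError(f"bad clinical table {path}: {exc}") from None
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index=False)
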