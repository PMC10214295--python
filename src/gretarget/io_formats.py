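"""Readers, writers and domain records for the standard files the pipeline touches.

Conventions (documented, not negotiable elsewhere in the package):

* BED coordinates are 0-based, half-open throughout.  Inputs transcribed
  from 1-based coordinate lists must be converted at the boundary with the
  explicit ``one_based=True`` flag of :func:`read_bed`.
* Chromosome names are taken verbatim; no ``chr``-prefix normalization.
* Differential-expression calls use a strict ``padj < alpha`` with a default
  ``alpha = 0.05``.
* Enhancer tables are TSV with columns
  ``chrom, start, end, target_gene, association_score``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_DE_ALPHA = 0.05

DNA_ALPHABET = "ACGT"


class FormatError(ValueError):
    """A file violates the dialect this package documents for its format."""


class SchemaError(FormatError):
    """A tabular file lacks required columns or carries duplicate keys."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A genomic region in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


DE_STATUSES = ("up", "down", "not_de", "untested")


def classify_de(log2fc: float | None, padj: float | None, alpha: float = DEFAULT_DE_ALPHA) -> str:
    """Assign a DE status from effect size and adjusted p (strict ``padj < alpha``)."""
    if log2fc is None or padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return "untested"
    if isinstance(log2fc, float) and math.isnan(log2fc):
        return "untested"
    if padj < alpha and log2fc > 0:
        return "up"
    if padj < alpha and log2fc < 0:
        return "down"
    return "not_de"


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS anchor and (optional) differential-expression call."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    symbol: str | None = None
    log2fc: float | None = None
    padj: float | None = None
    de_status: str = "untested"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError("tss must be non-negative")
        if self.de_status not in DE_STATUSES:
            raise ValidationError(f"invalid de_status {self.de_status!r}")
        if self.padj is not None and not math.isnan(self.padj) and not 0.0 <= self.padj <= 1.0:
            raise ValidationError(f"padj must lie in [0, 1], got {self.padj}")

    @property
    def is_de(self) -> bool:
        return self.de_status in ("up", "down")


@dataclass(frozen=True)
class OpenChromatinRegion:
    """An accessible-chromatin region carrying a chromatin-class label."""

    interval: GenomicInterval
    chromatin_class: str

    def __post_init__(self) -> None:
        if not self.chromatin_class:
            raise ValidationError("chromatin_class must be non-empty")


@dataclass(frozen=True)
class ClassWeightTable:
    """Chromatin class → non-negative weight (the class-frequency scores)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("class weight table must contain at least one class")
        for cls, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"class {cls!r} has negative weight {w}")

    def __getitem__(self, cls: str) -> float:
        return self.weights[cls]

    def __contains__(self, cls: str) -> bool:
        return cls in self.weights


@dataclass(frozen=True)
class EnhancerLink:
    """An enhancer element linked to a target gene with an association score."""

    interval: GenomicInterval
    target_gene: str
    association_score: float

    def __post_init__(self) -> None:
        if self.association_score < 0:
            raise ValidationError("association_score must be >= 0")
        if not self.target_gene:
            raise ValidationError("target_gene must be non-empty")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over A, C, G, T with a 0-order background.

    ``matrix`` holds raw column probabilities (rows = positions).  The
    pseudocount is applied lazily by :meth:`probabilities`, so that a
    write→read round trip preserves the raw matrix.
    """

    motif_id: str
    matrix: np.ndarray  # shape (L, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # shape (4,)
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValidationError("PWM matrix must have shape (L >= 1, 4)")
        if np.any(self.matrix < 0):
            raise ValidationError("PWM probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-2)[0]
        if bad.size:
            raise ValidationError(
                f"PWM {self.motif_id!r}: column {bad[0]} sums to {sums[bad[0]]:.4f}, not ~1"
            )
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError("background must be 4 probabilities summing to 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def probabilities(self) -> np.ndarray:
        """Pseudocounted, renormalized column probabilities (each row sums to 1)."""
        p = self.matrix + self.pseudocount * self.background[None, :]
        return p / p.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in np.argmax(self.matrix, axis=1))

    def with_background(self, background: np.ndarray) -> "PWM":
        return replace(self, background=np.asarray(background, dtype=float))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _split_bed_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_bed(
    path: str | Path,
    expect_class_column: bool = False,
    one_based: bool = False,
) -> list[GenomicInterval] | list[OpenChromatinRegion]:
    """Read BED3/BED4/BED6 records.

    With ``expect_class_column`` the 4th column is interpreted as a chromatin
    class label and :class:`OpenChromatinRegion` records are returned.
    ``one_based`` converts fully-closed 1-based starts at the boundary.
    """
    out: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_bed_line(line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                start = int(fields[1]) - (1 if one_based else 0)
                end = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else None
            try:
                iv = GenomicInterval(fields[0], start, end, name=name, score=score, strand=strand)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if expect_class_column:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: missing chromatin class column")
                out.append(OpenChromatinRegion(
                    GenomicInterval(fields[0], start, end), chromatin_class=name))
            else:
                out.append(iv)
    return out


def write_bed(records: Iterable[GenomicInterval | OpenChromatinRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, OpenChromatinRegion):
                iv, name = rec.interval, rec.chromatin_class
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
                continue
            cols = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.name is not None or rec.score is not None or rec.strand is not None:
                cols.append(rec.name if rec.name is not None else ".")
            if rec.score is not None or rec.strand is not None:
                cols.append(repr(rec.score) if rec.score is not None else ".")
            if rec.strand is not None:
                cols.append(rec.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# gene / DE tables (TSV with header)
# ---------------------------------------------------------------------------

_GENE_REQUIRED = ("gene_id", "chrom", "strand", "tss")


def read_gene_table(path: str | Path, alpha: float = DEFAULT_DE_ALPHA) -> list[GeneRecord]:
    """Read a TSV gene-annotation table; DE columns (log2fc, padj) are optional.

    ``de_status`` is assigned from ``padj < alpha`` and the sign of log2fc.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in _GENE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        log2fc = getattr(row, "log2fc", None)
        padj = getattr(row, "padj", None)
        log2fc = None if log2fc is None or (isinstance(log2fc, float) and math.isnan(log2fc)) else float(log2fc)
        padj = None if padj is None or (isinstance(padj, float) and math.isnan(padj)) else float(padj)
        symbol = getattr(row, "symbol", None)
        symbol = None if symbol is None or (isinstance(symbol, float) and math.isnan(symbol)) else str(symbol)
        records.append(GeneRecord(
            gene_id=str(row.gene_id), chrom=str(row.chrom), strand=str(row.strand),
            tss=int(row.tss), symbol=symbol, log2fc=log2fc, padj=padj,
            de_status=classify_de(log2fc, padj, alpha)))
    return records


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "symbol": [g.symbol if g.symbol is not None else "" for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "tss": [g.tss for g in genes],
        "log2fc": [g.log2fc if g.log2fc is not None else np.nan for g in genes],
        "padj": [g.padj if g.padj is not None else np.nan for g in genes],
    })
    df.to_csv(path, sep="\t", index=False)


def merge_de_results(
    genes: Sequence[GeneRecord],
    de_table: pd.DataFrame,
    alpha: float = DEFAULT_DE_ALPHA,
) -> list[GeneRecord]:
    """Attach a DE result table (columns gene_id, log2fc, padj) to annotation records."""
    for col in ("gene_id", "log2fc", "padj"):
        if col not in de_table.columns:
            raise SchemaError(f"DE table missing column {col!r}")
    if de_table["gene_id"].duplicated().any():
        raise ValidationError("DE table carries duplicate gene_id rows")
    lookup = de_table.set_index("gene_id")
    out = []
    for g in genes:
        if g.gene_id in lookup.index:
            l2fc = float(lookup.at[g.gene_id, "log2fc"])
            padj = float(lookup.at[g.gene_id, "padj"])
            out.append(replace(g, log2fc=l2fc, padj=padj,
                               de_status=classify_de(l2fc, padj, alpha)))
        else:
            out.append(replace(g, log2fc=None, padj=None, de_status="untested"))
    return out


# ---------------------------------------------------------------------------
# class weights / enhancer tables
# ---------------------------------------------------------------------------

def read_class_weights(path: str | Path) -> ClassWeightTable:
    df = pd.read_csv(path, sep="\t", dtype={"chromatin_class": str})
    for col in ("chromatin_class", "weight"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if df["chromatin_class"].duplicated().any():
        raise ValidationError(f"{path}: duplicate chromatin_class rows")
    return ClassWeightTable(dict(zip(df["chromatin_class"], df["weight"].astype(float))))


def write_class_weights(table: ClassWeightTable, path: str | Path) -> None:
    pd.DataFrame(
        {"chromatin_class": list(table.weights), "weight": list(table.weights.values())}
    ).to_csv(path, sep="\t", index=False)


def read_enhancer_table(path: str | Path) -> list[EnhancerLink]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "target_gene": str})
    for col in ("chrom", "start", "end", "target_gene", "association_score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return [
        EnhancerLink(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            target_gene=str(r.target_gene),
            association_score=float(r.association_score),
        )
        for r in df.itertuples(index=False)
    ]


def write_enhancer_table(links: Sequence[EnhancerLink], path: str | Path) -> None:
    pd.DataFrame({
        "chrom": [l.interval.chrom for l in links],
        "start": [l.interval.start for l in links],
        "end": [l.interval.end for l in links],
        "target_gene": [l.target_gene for l in links],
        "association_score": [l.association_score for l in links],
    }).to_csv(path, sep="\t", index=False)


def convert_genehancer_dump(path: str | Path) -> list[EnhancerLink]:  # pragma: no cover - stub
    """Converter stub for raw GeneHancer exports.

    The canonical enhancer input of this package is the 5-column TSV read by
    :func:`read_enhancer_table`.  Full GeneHancer dumps bundle every target
    gene of an element with its score inside a single attributes column; a
    converter must split that column into one (element, target, score) row
    per association and emit the 5-column dialect.  Not implemented because
    the dump schema varies between releases; map your export externally.
    """
    raise NotImplementedError("convert GeneHancer dumps to the 5-column TSV dialect first")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id → uppercase-sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path, pseudocount: float = 0.1) -> list[PWM]:
    """Read PWMs from MEME minimal text format.

    Letter-probability rows are parsed at full printed precision (the
    general-purpose motif parsers quantize them into integer counts).  The
    file background is attached to every motif; files without a background
    line get the uniform 0.25 default.
    """
    lines = Path(path).read_text().splitlines()
    if not any(line.startswith("MEME version") for line in lines):
        raise FormatError(f"{path}: not a MEME motif file (missing version line)")
    bg = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower().startswith("background letter frequencies"):
            # frequencies may wrap over several lines: letter/value pairs
            tokens: list[str] = []
            i += 1
            while i < len(lines) and lines[i].strip() and \
                    lines[i].split()[0] in ("A", "C", "G", "T"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            bg = np.array([freq.get(b, 0.0) for b in DNA_ALPHABET])
            if abs(bg.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"{path}: background frequencies sum to {bg.sum():.4f}")
            continue
        if stripped.startswith("MOTIF"):
            parts = stripped.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id!r} has no matrix")
                i += 1
            if i == len(lines):
                raise FormatError(f"{path}: motif {motif_id!r} has no matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                vals = lines[i].split()
                try:
                    row = [float(v) for v in vals]
                except ValueError:
                    break
                if len(row) != 4:
                    if rows:
                        break
                    raise FormatError(f"{path}: matrix row with {len(row)} columns")
                if abs(sum(row) - 1.0) > 1e-2:
                    raise ValidationError(
                        f"{path}: motif {motif_id!r} row {len(rows) + 1} sums to "
                        f"{sum(row):.4f}, not ~1")
                rows.append(row)
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r} has an empty matrix")
            pwms.append(PWM(motif_id=motif_id, matrix=np.array(rows),
                            background=bg.copy(), pseudocount=pseudocount))
            continue
        i += 1
    if not pwms:
        raise FormatError(f"{path}: no MOTIF entry found")
    return pwms


def write_meme_motifs(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal format (shared background from the first PWM)."""
    if not pwms:
        raise ValidationError("no motifs to write")
    bg = pwms[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.9f}" for i, b in enumerate(DNA_ALPHABET)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level YAML must be a mapping")
    return cfg
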