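"""Reading and writing ORF summary tables and FASTA files.

The ORF summary table is a tab-separated, UTF-8 text file with a mandatory
header row, one row per predicted ORF, in the style of the per-ORF table
emitted by co-assembly annotation pipelines.  Fixed columns::

    ORF_ID  Contig_ID  Taxon  Gene_name  KEGG  COG  Pfam
    Length_bp  Has_start  Has_stop  GC_fraction  TPM_<sample> ...

Multi-valued annotation cells (KEGG / COG / Pfam) are comma-separated; one
``TPM_<sample>`` column per sample carries the normalized abundance.  The
normalization convention is classic TPM: per-feature read counts divided by
feature length, rescaled so that each sample column sums to one million.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import IntegrityError, NormalizationError, TableFormatError

TPM_TOTAL = 1_000_000.0
TPM_PREFIX = "TPM_"

#: Fixed (non-TPM) columns of the ORF table dialect, in file order.
MANDATORY_COLUMNS = (
    "ORF_ID",
    "Contig_ID",
    "Taxon",
    "Gene_name",
    "KEGG",
    "COG",
    "Pfam",
    "Length_bp",
    "Has_start",
    "Has_stop",
    "GC_fraction",
)

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}
_KEGG_RE = re.compile(r"^K\d+$")


@dataclass
class OrfRecord:
    """One predicted ORF with taxonomy, annotation and per-sample abundance.

    Parameters
    ----------
    orf_id : str
        Unique ORF identifier within its table.
    contig_id : str
        Identifier of the contig the ORF was predicted on.
    taxon : str
        Semicolon-delimited lineage; the last field is the species-level
        tag, which may be ``unknown_<k>`` for unclassified species.
    gene_name : str
        Gene symbol, or empty when unannotated.
    annotations : set of str
        Orthogroup identifiers (KEGG K-numbers, COG ids, Pfam accessions).
    length_bp : int
        ORF length in base pairs (>= 3).
    has_start, has_stop : bool
        Completeness flags; an ORF is *complete* when both are true.
    gc_fraction : float
        G+C fraction of the ORF sequence, in [0, 1].
    tpm : dict of str -> float
        Per-sample normalized abundance (TPM units), all >= 0.
    """

    orf_id: str
    contig_id: str
    taxon: str
    gene_name: str = ""
    annotations: set[str] = field(default_factory=set)
    length_bp: int = 3
    has_start: bool = True
    has_stop: bool = True
    gc_fraction: float = 0.5
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_bp < 3:
            raise ValueError(
                f"ORF {self.orf_id!r}: length_bp must be >= 3, got {self.length_bp}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(
                f"ORF {self.orf_id!r}: gc_fraction must lie in [0, 1], "
                f"got {self.gc_fraction}"
            )
        for sample, value in self.tpm.items():
            if value < 0:
                raise ValueError(
                    f"ORF {self.orf_id!r}: negative TPM {value} in sample {sample!r}"
                )

    @property
    def species_tag(self) -> str:
        """Species-level tag: the last field of the lineage string."""
        return self.taxon.rsplit(";", 1)[-1].strip()

    @property
    def is_unknown_species(self) -> bool:
        return self.species_tag.startswith("unknown_")

    @property
    def is_complete(self) -> bool:
        """True when both start and stop codons were predicted."""
        return self.has_start and self.has_stop

    @property
    def is_orphan(self) -> bool:
        """True when the ORF has no annotation and no gene name."""
        return not self.annotations and not self.gene_name


class OrfTable:
    """An ordered collection of :class:`OrfRecord` over a fixed sample set.

    ``orf_id`` values are unique within a table.  The table does not have
    to be TPM-normalized; :meth:`normalized` returns a copy in which every
    sample column sums to one million.
    """

    def __init__(self, records: Sequence[OrfRecord], sample_ids: Sequence[str],
                 metadata: dict | None = None) -> None:
        seen: set[str] = set()
        for rec in records:
            if rec.orf_id in seen:
                raise IntegrityError(f"duplicate orf_id {rec.orf_id!r}")
            seen.add(rec.orf_id)
        self.records: list[OrfRecord] = list(records)
        self.sample_ids: list[str] = list(sample_ids)
        #: Free-form provenance (e.g. generator bookkeeping); not serialized.
        self.metadata: dict = metadata or {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OrfRecord]:
        return iter(self.records)

    def sample_total(self, sample: str) -> float:
        """Summed TPM of one sample column."""
        return float(sum(rec.tpm.get(sample, 0.0) for rec in self.records))

    def normalized(self) -> "OrfTable":
        """Return a copy rescaled so each sample column sums to 1e6 TPM."""
        totals = {s: self.sample_total(s) for s in self.sample_ids}
        for s, tot in totals.items():
            if tot <= 0:
                raise NormalizationError(f"sample {s!r} has zero total abundance")
        records = []
        for rec in self.records:
            tpm = {s: rec.tpm.get(s, 0.0) * TPM_TOTAL / totals[s]
                   for s in self.sample_ids}
            records.append(OrfRecord(
                orf_id=rec.orf_id, contig_id=rec.contig_id, taxon=rec.taxon,
                gene_name=rec.gene_name, annotations=set(rec.annotations),
                length_bp=rec.length_bp, has_start=rec.has_start,
                has_stop=rec.has_stop, gc_fraction=rec.gc_fraction, tpm=tpm))
        return OrfTable(records, self.sample_ids, dict(self.metadata))

    def to_dataframe(self) -> pd.DataFrame:
        """Render the table as a pandas DataFrame in the file dialect."""
        rows = []
        for rec in self.records:
            kegg = sorted(a for a in rec.annotations if _KEGG_RE.match(a))
            cog = sorted(a for a in rec.annotations if a.startswith("COG"))
            pfam = sorted(rec.annotations - set(kegg) - set(cog))
            row = {
                "ORF_ID": rec.orf_id,
                "Contig_ID": rec.contig_id,
                "Taxon": rec.taxon,
                "Gene_name": rec.gene_name,
                "KEGG": ",".join(kegg),
                "COG": ",".join(cog),
                "Pfam": ",".join(pfam),
                "Length_bp": rec.length_bp,
                "Has_start": int(rec.has_start),
                "Has_stop": int(rec.has_stop),
                "GC_fraction": rec.gc_fraction,
            }
            for s in self.sample_ids:
                row[TPM_PREFIX + s] = rec.tpm.get(s, 0.0)
            rows.append(row)
        columns = list(MANDATORY_COLUMNS) + [TPM_PREFIX + s for s in self.sample_ids]
        return pd.DataFrame(rows, columns=columns)


def _parse_bool(cell: str, column: str, row: int) -> bool:
    text = str(cell).strip()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {cell!r} in column {column}")


def _split_cell(cell) -> set[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    text = str(cell).strip()
    if not text:
        return set()
    return {part.strip() for part in text.split(",") if part.strip()}


def read_orf_table(path: str | Path) -> OrfTable:
    """Read an ORF summary table (TSV dialect described in the module docs).

    Raises
    ------
    TableFormatError
        If a mandatory column is missing.
    IntegrityError
        On duplicate ``ORF_ID`` values.
    ValueError
        On negative TPM or length, citing the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column {col!r} in {path}")
    tpm_cols = [c for c in df.columns if c.startswith(TPM_PREFIX)]
    sample_ids = [c[len(TPM_PREFIX):] for c in tpm_cols]

    records: list[OrfRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        length = int(float(row["Length_bp"]))
        if length <= 0:
            raise ValueError(f"row {idx}: non-positive Length_bp {length}")
        tpm = {}
        for s, col in zip(sample_ids, tpm_cols):
            value = float(row[col])
            if value < 0:
                raise ValueError(f"row {idx}: negative TPM {value} in column {col}")
            tpm[s] = value
        annotations = (_split_cell(row["KEGG"]) | _split_cell(row["COG"])
                       | _split_cell(row["Pfam"]))
        records.append(OrfRecord(
            orf_id=row["ORF_ID"],
            contig_id=row["Contig_ID"],
            taxon=row["Taxon"],
            gene_name=str(row["Gene_name"]).strip(),
            annotations=annotations,
            length_bp=length,
            has_start=_parse_bool(row["Has_start"], "Has_start", idx),
            has_stop=_parse_bool(row["Has_stop"], "Has_stop", idx),
            gc_fraction=float(row["GC_fraction"]),
            tpm=tpm,
        ))
    return OrfTable(records, sample_ids)


def write_orf_table(table: OrfTable, path: str | Path) -> None:
    """Write an :class:`OrfTable` in the TSV dialect (lossless round trip)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def normalize_tpm(raw_counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Convert per-ORF read counts to TPM.

    TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6 — counts are first
    length-normalized to rates and then rescaled so the sample sums to
    one million.

    Raises
    ------
    NormalizationError
        If every count is zero (sample total undefined).
    ValueError
        On mismatched input lengths, negative counts or non-positive lengths.
    """
    counts = np.asarray(raw_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if counts.shape != lens.shape:
        raise ValueError("raw_counts and lengths must have equal length")
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(lens <= 0):
        raise ValueError("lengths must be positive")
    rates = counts / lens
    total = rates.sum()
    if total <= 0:
        raise NormalizationError("all read counts are zero; TPM undefined")
    return rates / total * TPM_TOTAL


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered ``(id, sequence)`` pairs.

    Sequences are uppercased.  An empty file yields an empty list.

    Raises
    ------
    IntegrityError
        On duplicate record identifiers.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IntegrityError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq).upper()))
    return pairs


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapped at ``width`` columns."""
    records = (SeqRecord(Seq(seq), id=name, description="") for name, seq in pairs)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
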