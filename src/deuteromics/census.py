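"""Functional censuses over ORF tables.

Quantifies annotation categories three ways: a category census (share of
ORF *counts* and summed TPM per sample, e.g. for transposases), per-gene
TPM matrices (summed abundance of named genes or alias groups per
sample), and the orphan fraction (ORFs without any annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables_io import OrfRecord, OrfTable

__all__ = ["CategoryMatcher", "TRANSPOSASE_MATCHER", "CensusResult",
           "transposase_census", "gene_tpm_table", "orphan_fraction"]


@dataclass(frozen=True)
class CategoryMatcher:
    """Rule deciding whether an ORF belongs to a functional category.

    An ORF matches when its gene name contains one of ``keywords``
    (case-insensitive substring) or its annotations intersect
    ``orthogroups``.  This is a conservative, explicit rule: no fuzzy
    matching, and both criteria are user-overridable.
    """

    keywords: frozenset[str] = frozenset({"transposase"})
    orthogroups: frozenset[str] = frozenset({"COG2801", "COG2963"})
    description: str = "transposase keyword or IS3-family orthogroup"

    def __post_init__(self) -> None:
        if not self.keywords and not self.orthogroups:
            raise ConfigError("matcher needs at least one keyword or orthogroup")

    def matches(self, rec: OrfRecord) -> bool:
        name = rec.gene_name.lower()
        if any(kw.lower() in name for kw in self.keywords if kw):
            return True
        return bool(rec.annotations & self.orthogroups)


#: Default matcher: explicit transposase gene names plus the IS3-family
#: orthogroups COG2801/COG2963.
TRANSPOSASE_MATCHER = CategoryMatcher()


@dataclass
class CensusResult:
    """Per-sample and cross-sample summary of one functional category.

    ``per_sample_count_pct`` is 100 x (matching ORFs present) / (ORFs
    present) per sample, ``per_sample_tpm`` the summed TPM of matching
    ORFs.  Cross-sample means and sds are unweighted sample statistics
    (ddof = 1; the sd is NaN with a single sample).
    """

    per_sample_count_pct: dict[str, float]
    per_sample_tpm: dict[str, float]
    mean_count_pct: float
    sd_count_pct: float
    mean_tpm: float
    sd_tpm: float
    matcher_description: str
    n_matching: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        samples = list(self.per_sample_count_pct)
        return pd.DataFrame({
            "sample": samples,
            "count_pct": [self.per_sample_count_pct[s] for s in samples],
            "tpm": [self.per_sample_tpm[s] for s in samples],
        })


def transposase_census(table: OrfTable,
                       matcher: CategoryMatcher = TRANSPOSASE_MATCHER) -> CensusResult:
    """Census of a functional category (transposases by default).

    Per sample, the count percentage uses ORFs with TPM > 0 in that
    sample as the denominator, and the TPM value is the summed abundance
    of matching ORFs.  In a normalized table the matching TPM plus the
    complement TPM equals one million per sample.
    """
    if len(table) == 0:
        raise ConfigError("empty table")
    match_flags = [matcher.matches(rec) for rec in table]
    count_pct: dict[str, float] = {}
    tpm_sum: dict[str, float] = {}
    for s in table.sample_ids:
        present = match_present = 0
        total_tpm = 0.0
        for rec, is_match in zip(table, match_flags):
            v = rec.tpm.get(s, 0.0)
            if v > 0:
                present += 1
                if is_match:
                    match_present += 1
            if is_match:
                total_tpm += v
        count_pct[s] = 100.0 * match_present / present if present else 0.0
        tpm_sum[s] = total_tpm

    pct = np.array(list(count_pct.values()))
    tpm = np.array(list(tpm_sum.values()))
    sd_pct = float(pct.std(ddof=1)) if len(pct) > 1 else float("nan")
    sd_tpm = float(tpm.std(ddof=1)) if len(tpm) > 1 else float("nan")
    return CensusResult(
        per_sample_count_pct=count_pct, per_sample_tpm=tpm_sum,
        mean_count_pct=float(pct.mean()), sd_count_pct=sd_pct,
        mean_tpm=float(tpm.mean()), sd_tpm=sd_tpm,
        matcher_description=matcher.description,
        n_matching=int(sum(match_flags)))


def gene_tpm_table(table: OrfTable, gene_names: list[str]) -> pd.DataFrame:
    """Summed TPM per gene (rows) and sample (columns).

    Gene-name matching is case-insensitive and exact; an alias group
    written ``"ada/alkA"`` sums the TPM of all member names into one row.
    Genes absent from a sample get 0.
    """
    if not gene_names:
        raise ConfigError("gene list must be non-empty")
    data = {}
    for entry in gene_names:
        members = {m.strip().lower() for m in entry.split("/") if m.strip()}
        row = {s: 0.0 for s in table.sample_ids}
        for rec in table:
            if rec.gene_name.lower() in members:
                for s in table.sample_ids:
                    row[s] += rec.tpm.get(s, 0.0)
        data[entry] = row
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=table.sample_ids).loc[gene_names]


def orphan_fraction(table: OrfTable) -> float:
    """Percentage of ORFs with no annotation and no gene name."""
    if len(table) == 0:
        raise ConfigError("empty table")
    orphans = sum(1 for rec in table if rec.is_orphan)
    return 100.0 * orphans / len(table)
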