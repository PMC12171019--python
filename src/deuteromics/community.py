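"""Community-level statistics on ORF tables.

Covers abundance-weighted gene-length summaries, G+C content, per-sample
species richness (with or without unclassified ``unknown_<k>`` species
tags) and Jaccard presence/absence beta-diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import StatisticError
from .tables_io import OrfTable

__all__ = [
    "WeightedLengthResult", "weighted_gene_length", "gc_content",
    "species_richness", "species_set", "jaccard",
]


@dataclass
class WeightedLengthResult:
    """Abundance-weighted gene-length summary.

    ``mean_bp`` and ``sd_bp`` are the TPM-weighted mean and standard
    deviation of ORF lengths; ``n_used``/``n_excluded`` count the ORFs
    that entered, respectively failed, the completeness filter.
    """

    mean_bp: float
    sd_bp: float
    n_used: int
    n_excluded: int


def weighted_gene_length(table: OrfTable, sample: str | None = None,
                         require_complete: bool = True) -> WeightedLengthResult:
    """TPM-weighted mean and sd of predicted gene lengths.

    The weight of each ORF is its TPM in ``sample``, or its TPM summed
    across all samples when ``sample`` is None (pooled scope, matching a
    co-assembled table where one ORF is shared by all samples).  When
    ``require_complete`` is true, only ORFs with both a start and a stop
    codon are used.  The sd uses the same weights as the mean (frequency
    weights, no small-sample correction):

        mean = sum(L_i w_i) / sum(w_i)
        sd   = sqrt( sum(w_i (L_i - mean)^2) / sum(w_i) )
    """
    if sample is not None and sample not in table.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    lengths, weights = [], []
    n_excluded = 0
    for rec in table:
        if require_complete and not rec.is_complete:
            n_excluded += 1
            continue
        if sample is None:
            w = sum(rec.tpm.get(s, 0.0) for s in table.sample_ids)
        else:
            w = rec.tpm.get(sample, 0.0)
        lengths.append(rec.length_bp)
        weights.append(w)
    if not lengths:
        raise StatisticError("no ORFs left after completeness filtering")
    L = np.asarray(lengths, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise StatisticError("total weight is zero in the requested scope")
    mean = float((L * w).sum() / total)
    var = float((w * (L - mean) ** 2).sum() / total)
    return WeightedLengthResult(mean_bp=mean, sd_bp=float(np.sqrt(var)),
                                n_used=len(lengths), n_excluded=n_excluded)


def gc_content(source: str | OrfTable,
               weights: Sequence[float] | None = None) -> float:
    """G+C content in [0, 1].

    For a nucleotide string: the fraction of G/C bases.  For an
    :class:`OrfTable`: the mean of per-record ``gc_fraction`` values,
    weighted by ``weights`` (e.g. TPM) when given, unweighted otherwise.
    """
    if isinstance(source, str):
        seq = source.upper()
        if not seq:
            raise StatisticError("empty sequence")
        return sum(1 for ch in seq if ch in "GC") / len(seq)
    if len(source) == 0:
        raise StatisticError("empty table")
    gc = np.array([rec.gc_fraction for rec in source], dtype=float)
    if weights is None:
        return float(gc.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != gc.shape:
        raise ValueError("weights must have one entry per record")
    if w.sum() <= 0:
        raise StatisticError("total weight is zero")
    return float((gc * w).sum() / w.sum())


def species_set(table: OrfTable, sample: str,
                include_unknowns: bool = False) -> set[str]:
    """Species tags present (TPM > 0) in one sample.

    ``unknown_<k>`` tags are excluded unless ``include_unknowns``.
    """
    if sample not in table.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    present = set()
    for rec in table:
        if rec.tpm.get(sample, 0.0) > 0:
            if include_unknowns or not rec.is_unknown_species:
                present.add(rec.species_tag)
    return present


def species_richness(table: OrfTable, sample: str,
                     include_unknowns: bool = False) -> int:
    """Number of distinct species tags present (TPM > 0) in a sample."""
    return len(species_set(table, sample, include_unknowns))


def jaccard(set_a: set, set_b: set) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| on presence/absence sets.

    Used as a beta-diversity proxy between communities when no spatial
    overlap data are available.  Undefined for two empty sets.
    """
    if not set_a and not set_b:
        raise StatisticError("Jaccard undefined for two empty sets")
    union = set_a | set_b
    return len(set_a & set_b) / len(union)
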