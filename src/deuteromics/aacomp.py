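"""Amino-acid composition statistics for protein groups.

Relative composition is the per-sequence frequency vector over the 20
standard residues (non-standard symbols and gaps dropped before
normalization).  Within-group coherence is summarized as the mean Pearson
correlation over all unordered pairs of composition rows, and two groups
are compared residue-by-residue with unpaired t-tests, classifying each
residue as *enriched*, *depleted* or *same* in the first group relative
to the second.

The 20 columns of a composition matrix are compositionally dependent
(each row sums to one); the per-residue tests ignore this dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatisticError

#: Standard amino acids in alphabetical one-letter order (matrix columns).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class AaCompositionMatrix:
    """Per-sequence relative amino-acid frequencies for one group.

    ``data`` has one row per sequence and 20 columns ordered as
    :data:`AA_ALPHABET`; each row sums to one.
    """

    data: np.ndarray
    group_label: str
    sequence_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(AA_ALPHABET):
            raise ValueError("composition matrix must be (n_sequences, 20)")
        if len(self.sequence_ids) != self.data.shape[0]:
            raise ValueError("sequence_ids length must match number of rows")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if not np.allclose(self.data.sum(axis=1), 1.0, rtol=1e-9, atol=1e-9):
            raise ValueError("every composition row must sum to 1")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sequence_ids,
                            columns=list(AA_ALPHABET))


def composition_matrix(records: Sequence[tuple[str, str]],
                       group_label: str) -> AaCompositionMatrix:
    """Relative composition rows from ``(id, sequence)`` amino-acid records.

    Non-standard symbols (X, B, Z, *, gaps, ...) are dropped before
    normalization; a sequence left with zero standard residues is an error.
    """
    if not records:
        raise ValueError("no sequences given")
    rows = np.zeros((len(records), len(AA_ALPHABET)))
    ids = []
    for i, (name, seq) in enumerate(records):
        counts = np.zeros(len(AA_ALPHABET))
        for ch in seq.upper():
            j = _AA_INDEX.get(ch)
            if j is not None:
                counts[j] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sequence {name!r} has no standard residues")
        rows[i] = counts / total
        ids.append(name)
    return AaCompositionMatrix(rows, group_label, ids)


def group_self_correlation(matrix: AaCompositionMatrix) -> float:
    """Mean Pearson correlation over all unordered pairs of rows.

    Pairs involving a constant row (zero variance) are skipped with a
    warning; if every pair is skipped a :class:`StatisticError` is raised.
    """
    X = matrix.data
    if X.shape[0] < 2:
        raise StatisticError("self-correlation needs at least two sequences")
    sd = X.std(axis=1)
    constant = sd < 1e-12  # tolerance absorbs summation rounding
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant composition row(s) skipped "
            "in self-correlation", stacklevel=2)
    keep = ~constant
    if keep.sum() < 2:
        raise StatisticError("all row pairs degenerate; self-correlation undefined")
    corr = np.corrcoef(X[keep])
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


@dataclass
class EnrichmentResult:
    """Residue-wise two-group comparison.

    ``per_residue`` has one row per amino acid with the group means, the
    t statistic, the raw and adjusted p-values and the class label;
    ``counts`` is ``(n_enriched, n_depleted, n_same)`` and always sums
    to 20.
    """

    per_residue: pd.DataFrame
    counts: tuple[int, int, int]
    alpha: float
    correction: str

    @property
    def classes(self) -> pd.Series:
        return self.per_residue["class"]


def enrichment_test(a: AaCompositionMatrix, b: AaCompositionMatrix,
                    alpha: float = 0.05, correction: str = "none",
                    equal_var: bool = False) -> EnrichmentResult:
    """Classify each residue as enriched/depleted in group ``a`` vs ``b``.

    Per residue, an unpaired t-test (Welch by default; Student with
    ``equal_var=True``) compares the two groups' frequency columns.  A
    residue is *enriched* when the group-``a`` mean is higher and the
    (optionally Benjamini–Hochberg-adjusted) p-value is below ``alpha``,
    *depleted* when lower and significant, *same* otherwise.  Residues
    with zero variance in both groups and equal means are *same* with
    p = 1 by convention.
    """
    if a.n_sequences < 2 or b.n_sequences < 2:
        raise StatisticError("each group needs at least two sequences")
    if correction not in ("none", "benjamini-hochberg", "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    mean_a = a.data.mean(axis=0)
    mean_b = b.data.mean(axis=0)
    t_stat = np.empty(len(AA_ALPHABET))
    p_raw = np.empty(len(AA_ALPHABET))
    for j in range(len(AA_ALPHABET)):
        xa, xb = a.data[:, j], b.data[:, j]
        if xa.std() == 0 and xb.std() == 0:
            # degenerate columns: identical constants are trivially "same"
            t_stat[j] = 0.0
            p_raw[j] = 1.0 if mean_a[j] == mean_b[j] else 0.0
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        t_stat[j] = t
        p_raw[j] = p

    if correction in ("benjamini-hochberg", "bh"):
        adjusted = multipletests(p_raw, method="fdr_bh")[1]
    else:
        adjusted = p_raw.copy()

    classes = []
    for j in range(len(AA_ALPHABET)):
        if adjusted[j] < alpha and mean_a[j] > mean_b[j]:
            classes.append("enriched")
        elif adjusted[j] < alpha and mean_a[j] < mean_b[j]:
            classes.append("depleted")
        else:
            classes.append("same")

    per_residue = pd.DataFrame({
        "residue": list(AA_ALPHABET),
        "mean_a": mean_a, "mean_b": mean_b,
        "t_statistic": t_stat, "p_value": p_raw, "adjusted_p": adjusted,
        "class": classes,
    }).set_index("residue")
    counts = (classes.count("enriched"), classes.count("depleted"),
              classes.count("same"))
    return EnrichmentResult(per_residue=per_residue, counts=counts,
                            alpha=alpha, correction=correction)
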