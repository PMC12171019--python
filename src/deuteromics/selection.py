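"""Nei–Gojobori (1986) pairwise ka/ks estimation.

The NG86 counting method classifies each of the three positions of a sense
codon by the fraction of single-nucleotide changes that are synonymous,
giving per-codon synonymous (s) and nonsynonymous (n) site counts with
s + n = 3.  Differences between two aligned codons are classified directly
when one position differs; when two or three positions differ, every
ordering of single-nucleotide steps is enumerated, orderings that pass
through a stop codon are discarded, and the synonymous/nonsynonymous step
counts are averaged over the remaining orderings with equal weight.  The
resulting proportions pS = Sd/S and pN = Nd/N are corrected for multiple
hits with the Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p), and the
ratio dN/dS classifies the pair as evolving under purifying (< 1),
neutral (~ 1) or positive (> 1) selection.

Conventions (the common NG86 practice):

* single-nucleotide changes that would create a stop codon count as
  nonsynonymous when tallying *sites*;
* multi-step *pathways* through stop codons are excluded; if every pathway
  passes through a stop, all pathways are used with stop-involving steps
  counted nonsynonymous.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import DeuteromicsError

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_table.forward_table))
_AA = dict(_table.forward_table)

#: Default dN/dS band treated as "approximately neutral".
DEFAULT_NEUTRAL_BAND = (0.9, 1.1)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, ``*`` for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return _AA[codon]
    except KeyError:
        raise ValueError(f"not a standard-code codon: {codon!r}") from None


def _require_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not a valid input")
    if codon not in _AA:
        raise ValueError(f"not a standard-code codon: {codon!r}")


@dataclass(frozen=True)
class CodonSequencePair:
    """Two codon-aligned nucleotide sequences of equal length.

    Lengths must be equal and divisible by three; the alphabet is ACGT and
    neither sequence may contain a stop codon in frame.
    """

    seq_a: str
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(
                f"aligned sequences differ in length ({len(a)} vs {len(b)})")
        if len(a) % 3 != 0:
            raise ValueError(f"alignment length {len(a)} is not a codon multiple")
        if set(a + b) - set(NUCLEOTIDES):
            raise ValueError("sequences must use the ACGT alphabet only")
        for seq, name in ((a, self.id_a), (b, self.id_b)):
            for codon in _codons(seq):
                if codon in STOP_CODONS:
                    raise ValueError(f"sequence {name!r} contains stop codon {codon}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


def _codons(seq: str) -> Iterable[str]:
    return (seq[i:i + 3] for i in range(0, len(seq), 3))


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of a sense codon.

    At each of the three positions, the fraction of the three possible
    single-nucleotide changes that preserve the encoded amino acid is the
    synonymous site contribution; changes creating a stop codon count as
    nonsynonymous.  Returns ``(s, n)`` with ``s + n == 3``.
    """
    _require_sense(codon)
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant not in STOP_CODONS and _AA[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _classify_step(x: str, y: str) -> tuple[float, float]:
    """(sd, nd) of one single-nucleotide step; stop-involving steps are
    nonsynonymous (fallback convention only — normal pathways never
    contain stops)."""
    if x in STOP_CODONS or y in STOP_CODONS:
        return 0.0, 1.0
    return (1.0, 0.0) if _AA[x] == _AA[y] else (0.0, 1.0)


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    Identical codons give (0, 0); a single difference is classified
    directly; two or three differences average over all orderings of
    single-nucleotide steps, excluding orderings whose intermediate codons
    are stops.  If every ordering passes through a stop, all orderings are
    retained with stop-involving steps counted as nonsynonymous.
    """
    _require_sense(codon_a)
    _require_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        return _classify_step(codon_a, codon_b)

    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            step_s, step_n = _classify_step(current, nxt)
            sd += step_s
            nd += step_n
            current = nxt
        fallback.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))

    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Returns ``nan`` when p >= 0.75 (saturated; the log argument is
    non-positive).
    """
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass
class KaKsEstimate:
    """NG86 estimate for one aligned codon sequence pair.

    ``S``/``N`` are mean synonymous/nonsynonymous site counts (averaged
    over the two sequences), ``Sd``/``Nd`` the pathway-averaged difference
    counts, ``pS``/``pN`` the proportions, ``dS``/``dN`` the Jukes–Cantor
    distances and ``ratio`` = dN/dS.  ``regime`` is one of ``purifying``,
    ``neutral``, ``positive`` or ``undefined``; ``saturated`` flags a
    proportion >= 3/4 for which the distance is undefined.
    """

    id_a: str
    id_b: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float
    regime: str
    saturated: bool = False


def ng86(pair: CodonSequencePair,
         neutral_band: tuple[float, float] = DEFAULT_NEUTRAL_BAND) -> KaKsEstimate:
    """Estimate dN/dS for one codon-aligned pair with the NG86 method.

    The selection regime is ``purifying`` when dN/dS is below the neutral
    band, ``neutral`` inside it, ``positive`` above it (including the
    dS = 0, dN > 0 case, reported with an infinite ratio) and
    ``undefined`` when the sequences are identical or a distance is
    saturated.
    """
    if pair.n_codons < 1:
        raise ValueError("pair must contain at least one codon")
    lo, hi = neutral_band
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid neutral band ({lo}, {hi})")

    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pair.codon_columns():
        sa, _ = count_sites(ca)
        sb, _ = count_sites(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = count_differences(ca, cb)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * pair.n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = math.isnan(dS) or math.isnan(dN)

    if saturated:
        ratio, regime = math.nan, "undefined"
    elif sd == 0.0 and nd == 0.0:
        ratio, regime = math.nan, "undefined"
    elif dS == 0.0:
        ratio, regime = math.inf, "positive"
    else:
        ratio = dN / dS
        if ratio < lo:
            regime = "purifying"
        elif ratio > hi:
            regime = "positive"
        else:
            regime = "neutral"

    return KaKsEstimate(
        id_a=pair.id_a, id_b=pair.id_b, n_codons=pair.n_codons,
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN,
        ratio=ratio, regime=regime, saturated=saturated)


@dataclass
class KaKsScreen:
    """Batch NG86 result: one row per pair plus regime summary counts."""

    table: pd.DataFrame
    regime_counts: dict[str, int]
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)


_SCREEN_COLUMNS = ["id_a", "id_b", "n_codons", "S", "N", "Sd", "Nd",
                   "pS", "pN", "dS", "dN", "ratio", "regime", "saturated"]


def kaks_screen(pairs: Sequence[CodonSequencePair],
                neutral_band: tuple[float, float] = DEFAULT_NEUTRAL_BAND) -> KaKsScreen:
    """Run :func:`ng86` over a batch of pairs.

    Per-pair failures are logged and collected in ``errors`` rather than
    aborting the batch; rows keep the input order.
    """
    rows = []
    errors: list[tuple[int, str]] = []
    for i, pair in enumerate(pairs):
        try:
            est = ng86(pair, neutral_band=neutral_band)
        except (ValueError, TypeError, AttributeError, DeuteromicsError) as exc:
            logger.warning("pair %d failed: %s", i, exc)
            errors.append((i, str(exc)))
            continue
        rows.append({c: getattr(est, c) for c in _SCREEN_COLUMNS})
    table = pd.DataFrame(rows, columns=_SCREEN_COLUMNS)
    counts = {reg: 0 for reg in ("purifying", "neutral", "positive", "undefined")}
    for reg in table["regime"]:
        counts[reg] += 1
    return KaKsScreen(table=table, regime_counts=counts, errors=errors)
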