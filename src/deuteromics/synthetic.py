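"""Synthetic inputs with the statistical structure the analyses assume.

Four seeded generators cover every input the pipeline consumes:

* :func:`generate_orf_table` — a multi-sample ORF summary table whose
  per-taxon variant richness follows d = c * A^gamma with Poisson
  scatter, lognormal-jittered taxon abundances, truncated-lognormal gene
  lengths, per-sample TPM normalization and controllable transposase /
  orphan / unknown-species fractions;
* :func:`generate_codon_pair` — an ancestor/descendant codon alignment
  evolved under a chosen nonsynonymous/synonymous rate ratio omega;
* :func:`generate_aa_groups` — two amino-acid composition matrices whose
  group means differ by a chosen per-residue effect profile, with
  Dirichlet noise keeping rows on the simplex;
* :func:`generate_presence_sets` — per-sample species sets with exact
  sizes and pairwise intersections.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .aacomp import AA_ALPHABET, AaCompositionMatrix
from .errors import ConfigError
from .selection import NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, CodonSequencePair, translate_codon
from .tables_io import TPM_TOTAL, OrfRecord, OrfTable

__all__ = [
    "CommunityConfig", "OmegaConfig", "generate_orf_table",
    "generate_codon_pair", "generate_aa_groups", "generate_presence_sets",
]


@dataclass
class CommunityConfig:
    """Parameters of a synthetic bacterial community ORF table.

    Defaults emulate the heavy-water drum metagenomes: 319 taxa per
    environment, richness slope gamma = 0.757, a 2.71% transposase ORF
    fraction, 5.95% orphan ORFs, G+C centred on 0.663 and gene lengths
    from a right-skewed lognormal truncated to [60, 8748] bp.

    ``noiseless`` replaces Poisson richness scatter by rounding and snaps
    each taxon's abundance back onto the generating law (diagnostic mode
    for exact-recovery tests); ``normalize`` controls the final per-sample
    rescaling to one million TPM.
    """

    n_taxa: int = 319
    n_orfs: int = 50_000
    n_samples: int = 3
    abundance_log10_range: tuple[float, float] = (0.0, 4.0)
    richness_intercept: float = 1.0       # c: expected variants at A = 1
    richness_slope: float = 0.757         # gamma
    transposase_fraction: float = 0.0271
    transposase_tpm_share: float | None = None   # fraction of each sample's TPM
    orphan_fraction: float = 0.0595
    unknown_fraction: float = 0.35        # share of taxa with unknown species tag
    length_median_bp: float = 700.0
    length_log_sigma: float = 0.45        # sigma of ln(length)
    min_bp: int = 60
    max_bp: int = 8748
    gc_mean: float = 0.663
    gc_sd: float = 0.05
    completeness_prob: float = 0.95       # P(has_start) = P(has_stop)
    sample_log10_jitter_sd: float = 0.1   # per-sample lognormal abundance jitter
    dirichlet_evenness: float = 5.0       # within-taxon ORF abundance evenness
    noiseless: bool = False
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_samples < 1:
            raise ConfigError("n_taxa and n_samples must be positive")
        if self.n_orfs < self.n_taxa:
            raise ConfigError("n_orfs must be >= n_taxa")
        if not 0 <= self.transposase_fraction <= 1:
            raise ConfigError("transposase_fraction must lie in [0, 1]")
        if self.transposase_tpm_share is not None and not (
                0 <= self.transposase_tpm_share < 1):
            raise ConfigError("transposase_tpm_share must lie in [0, 1)")
        if not 0 <= self.orphan_fraction <= 1:
            raise ConfigError("orphan_fraction must lie in [0, 1]")
        if self.richness_intercept <= 0:
            raise ConfigError("richness_intercept must be positive")
        if self.min_bp < 3 or self.max_bp < self.min_bp:
            raise ConfigError("invalid length bounds")
        lo, hi = self.abundance_log10_range
        if hi < lo:
            raise ConfigError("abundance_log10_range must be (lo, hi) with lo <= hi")


def _taxon_names(cfg: CommunityConfig, rng: np.random.Generator) -> list[str]:
    n_unknown = int(round(cfg.n_taxa * cfg.unknown_fraction))
    flags = np.zeros(cfg.n_taxa, dtype=bool)
    flags[rng.choice(cfg.n_taxa, size=n_unknown, replace=False)] = True
    names = []
    for i, unknown in enumerate(flags):
        lineage = (f"Bacteria;Phylum_{i % 7};Class_{i % 13};Order_{i % 17};"
                   f"Family_{i % 23};Genus_{i}")
        tag = f"unknown_{i}" if unknown else f"Species_{i}"
        names.append(f"{lineage};{tag}")
    return names


def _truncated_lognormal_lengths(n: int, cfg: CommunityConfig,
                                 rng: np.random.Generator) -> np.ndarray:
    """Gene lengths in bp: lognormal, truncated by resampling, rounded to
    codon multiples within the bounds."""
    mu = np.log(cfg.length_median_bp)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(mu, cfg.length_log_sigma, size=todo.size)
        ok = (draw >= cfg.min_bp) & (draw <= cfg.max_bp)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    lengths = (np.rint(out / 3.0) * 3).astype(int)
    return np.clip(lengths, max(cfg.min_bp, 3), cfg.max_bp)


def generate_orf_table(config: CommunityConfig) -> OrfTable:
    """Draw a synthetic ORF summary table.

    Per-taxon log10 abundances are uniform on ``abundance_log10_range``
    and rescaled so the expected total richness matches ``n_orfs`` (the
    rescaling preserves the generating law with the same c and gamma).
    Expected richness per taxon is c * A^gamma; realized richness is
    Poisson (or rounded, in noiseless mode).  Taxa whose realized
    richness is zero appear in ``table.metadata['zero_richness_taxa']``.
    Each ORF receives a truncated-lognormal length, clipped-normal G+C,
    independent Bernoulli completeness flags and, with probability
    ``transposase_fraction``, a transposase label (gene name plus an
    IS3-family orthogroup).  Per-sample TPM columns are normalized to one
    million unless ``normalize`` is off.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = _taxon_names(cfg, rng)

    lo, hi = cfg.abundance_log10_range
    A = 10.0 ** rng.uniform(lo, hi, size=cfg.n_taxa)
    c, gamma = cfg.richness_intercept, cfg.richness_slope
    expected = c * A ** gamma
    if gamma != 0 and expected.sum() > 0:
        # scale abundances so total expected richness hits n_orfs; the
        # power law in (A, d) is preserved with the same c and gamma
        A *= (cfg.n_orfs / expected.sum()) ** (1.0 / gamma)
        expected = c * A ** gamma

    if cfg.noiseless:
        d_obs = np.rint(expected).astype(int)
        positive = d_obs > 0
        # snap abundance onto the law so points are exactly log-linear
        if gamma != 0:
            A[positive] = (d_obs[positive] / c) ** (1.0 / gamma)
    else:
        d_obs = rng.poisson(expected)

    zero_taxa = [names[i].rsplit(";", 1)[-1]
                 for i in range(cfg.n_taxa) if d_obs[i] == 0]

    n_rows = int(d_obs.sum())
    if n_rows == 0:
        raise ConfigError("community realized zero ORFs; enlarge n_orfs or c")
    taxon_idx = np.repeat(np.arange(cfg.n_taxa), d_obs)

    lengths = _truncated_lognormal_lengths(n_rows, cfg, rng)
    gc = np.clip(rng.normal(cfg.gc_mean, cfg.gc_sd, size=n_rows), 0.0, 1.0)
    has_start = rng.random(n_rows) < cfg.completeness_prob
    has_stop = rng.random(n_rows) < cfg.completeness_prob
    is_transposase = rng.random(n_rows) < cfg.transposase_fraction
    is_orphan = (~is_transposase) & (rng.random(n_rows) < cfg.orphan_fraction)
    is_cog = rng.random(n_rows) < 0.5  # which IS3 orthogroup a transposase gets

    # per-sample taxon abundances: base abundance with lognormal jitter
    jitter_sd = 0.0 if cfg.noiseless else cfg.sample_log10_jitter_sd
    sample_ids = [f"S{k + 1}" for k in range(cfg.n_samples)]
    taxon_sample_A = A[:, None] * 10.0 ** rng.normal(
        0.0, jitter_sd, size=(cfg.n_taxa, cfg.n_samples))

    # split each taxon's abundance across its ORFs
    weights = np.empty((n_rows, cfg.n_samples))
    row = 0
    for t in range(cfg.n_taxa):
        k = int(d_obs[t])
        if k == 0:
            continue
        if cfg.noiseless:
            share = np.full((k, cfg.n_samples), 1.0 / k)
        else:
            share = rng.dirichlet(np.full(k, cfg.dirichlet_evenness),
                                  size=cfg.n_samples).T
        weights[row:row + k] = share * taxon_sample_A[t]
        row += k

    if cfg.transposase_tpm_share is not None and is_transposase.any():
        # rescale so transposase ORFs hold exactly the requested share of
        # each sample's abundance (before the final renormalization)
        share = cfg.transposase_tpm_share
        t_sum = weights[is_transposase].sum(axis=0)
        o_sum = weights[~is_transposase].sum(axis=0)
        weights[is_transposase] *= share / t_sum
        weights[~is_transposase] *= (1.0 - share) / o_sum

    if cfg.normalize:
        weights = weights / weights.sum(axis=0) * TPM_TOTAL

    records = []
    for i in range(n_rows):
        t = taxon_idx[i]
        if is_transposase[i]:
            gene_name = "transposase"
            annotations = {"COG2801" if is_cog[i] else "COG2963"}
        elif is_orphan[i]:
            gene_name = ""
            annotations = set()
        else:
            gene_name = f"gene_{i % 997}"
            annotations = {f"K{(i * 7) % 20000:05d}"}
        records.append(OrfRecord(
            orf_id=f"ORF_{i:06d}",
            contig_id=f"contig_{t:04d}",
            taxon=names[t],
            gene_name=gene_name,
            annotations=annotations,
            length_bp=int(lengths[i]),
            has_start=bool(has_start[i]),
            has_stop=bool(has_stop[i]),
            gc_fraction=float(gc[i]),
            tpm={s: float(weights[i, k]) for k, s in enumerate(sample_ids)},
        ))
    return OrfTable(records, sample_ids,
                    metadata={"zero_richness_taxa": zero_taxa,
                              "config": cfg})


@dataclass
class OmegaConfig:
    """Parameters of a simulated codon-pair divergence.

    ``omega`` is the nonsynonymous/synonymous rate ratio enforced during
    evolution, ``n_events`` the number of proposed single-nucleotide
    substitutions applied to the ancestor.
    """

    omega: float = 1.0
    n_codons: int = 300
    n_events: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ConfigError("omega must be non-negative")
        if self.n_codons < 1:
            raise ConfigError("n_codons must be positive")
        if self.n_events < 0:
            raise ConfigError("n_events must be non-negative")


def generate_codon_pair(config: OmegaConfig) -> CodonSequencePair:
    """Evolve a descendant from a random sense-codon ancestor.

    Each of ``n_events`` proposals mutates one random position to a
    random different nucleotide.  Proposals creating a stop codon are
    rejected; synonymous proposals are accepted with probability
    1 / (1 + omega) and nonsynonymous ones with probability
    omega / (1 + omega), so accepted nonsynonymous and synonymous changes
    occur at rate ratio omega per proposal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    codons = [SENSE_CODONS[i]
              for i in rng.integers(0, len(SENSE_CODONS), size=cfg.n_codons)]
    ancestor = "".join(codons)
    descendant = list(ancestor)
    p_nonsyn = cfg.omega / (1.0 + cfg.omega)
    p_syn = 1.0 / (1.0 + cfg.omega)
    for _ in range(cfg.n_events):
        pos = int(rng.integers(0, len(descendant)))
        old = descendant[pos]
        r = int(rng.integers(0, 3))
        if r >= NUCLEOTIDES.index(old):  # uniform over the 3 other bases
            r += 1
        new = NUCLEOTIDES[r]
        start = pos - pos % 3
        codon_old = "".join(descendant[start:start + 3])
        codon_new = codon_old[:pos - start] + new + codon_old[pos - start + 1:]
        if codon_new in STOP_CODONS:
            continue
        synonymous = translate_codon(codon_new) == translate_codon(codon_old)
        accept_p = p_syn if synonymous else p_nonsyn
        if rng.random() < accept_p:
            descendant[pos] = new
    return CodonSequencePair(seq_a=ancestor, seq_b="".join(descendant),
                             id_a="ancestor", id_b="descendant")


def generate_aa_groups(n1: int, n2: int,
                       effect_profile: Sequence[float] | None = None,
                       seed: int = 0, concentration: float = 500.0,
                       base: Sequence[float] | None = None,
                       labels: tuple[str, str] = ("group_a", "group_b"),
                       ) -> tuple[AaCompositionMatrix, AaCompositionMatrix]:
    """Two composition matrices whose group means differ by a profile.

    Group means are ``base + profile/2`` and ``base - profile/2`` (the
    default base is the uniform composition 0.05); per-sequence rows are
    Dirichlet draws around the group mean with the given concentration,
    which keeps every row on the 20-simplex.  Default group sizes in the
    package's worked examples are 129 and 70 sequences.
    """
    if n1 < 1 or n2 < 1:
        raise ConfigError("group sizes must be positive")
    k = len(AA_ALPHABET)
    base_v = (np.full(k, 1.0 / k) if base is None
              else np.asarray(base, dtype=float))
    profile = (np.zeros(k) if effect_profile is None
               else np.asarray(effect_profile, dtype=float))
    if base_v.shape != (k,) or profile.shape != (k,):
        raise ConfigError(f"base and effect_profile must have length {k}")
    mean_a = base_v + profile / 2.0
    mean_b = base_v - profile / 2.0
    if np.any(mean_a <= 0) or np.any(mean_a >= 1) or \
       np.any(mean_b <= 0) or np.any(mean_b >= 1):
        raise ConfigError("effect profile pushes expected frequencies out of (0, 1)")
    mean_a = mean_a / mean_a.sum()
    mean_b = mean_b / mean_b.sum()
    rng = np.random.default_rng(seed)
    rows_a = rng.dirichlet(concentration * mean_a, size=n1)
    rows_b = rng.dirichlet(concentration * mean_b, size=n2)
    mat_a = AaCompositionMatrix(rows_a, labels[0],
                                [f"{labels[0]}_{i}" for i in range(n1)])
    mat_b = AaCompositionMatrix(rows_b, labels[1],
                                [f"{labels[1]}_{i}" for i in range(n2)])
    return mat_a, mat_b


def generate_presence_sets(sizes: Sequence[int],
                           overlaps: Mapping[tuple[int, int], int],
                           seed: int = 0) -> list[set[str]]:
    """Species sets with exact sizes and pairwise intersection counts.

    ``overlaps`` maps index pairs ``(i, j)`` (i < j) to the required
    intersection size; missing pairs default to 0.  Construction uses a
    shared pool (of size equal to the minimum requested pairwise overlap,
    the default for higher-order overlaps), pair-exclusive pools and
    private labels.  Infeasible requests raise :class:`ConfigError`.
    """
    n = len(sizes)
    if n < 2:
        raise ConfigError("need at least two samples")
    ov = {}
    for (i, j), v in overlaps.items():
        if not (0 <= i < j < n):
            raise ConfigError(f"bad overlap key {(i, j)}")
        if v < 0 or v > min(sizes[i], sizes[j]):
            raise ConfigError(
                f"overlap {v} for pair {(i, j)} exceeds min size")
        ov[(i, j)] = int(v)
    for pair in combinations(range(n), 2):
        ov.setdefault(pair, 0)

    shared_all = min(ov.values()) if n > 2 else ov[(0, 1)]
    label = iter(f"sp_{i}" for i in range(10 * (sum(sizes) + 1)))
    sets: list[set[str]] = [set() for _ in range(n)]
    pool = [next(label) for _ in range(shared_all)]
    for s in sets:
        s.update(pool)
    for (i, j), v in ov.items():
        extra = v - shared_all
        if extra < 0:
            raise ConfigError(
                "pairwise overlaps inconsistent with the shared-pool "
                f"construction (pair {(i, j)} below the common overlap)")
        pool = [next(label) for _ in range(extra)]
        sets[i].update(pool)
        sets[j].update(pool)
    rng = np.random.default_rng(seed)
    for i, target in enumerate(sizes):
        if len(sets[i]) > target:
            raise ConfigError(
                f"sample {i}: overlaps require {len(sets[i])} species, "
                f"but size is {target}")
        n_private = target - len(sets[i])
        # seeded suffix keeps private labels sample-specific and reproducible
        offset = int(rng.integers(0, 1_000_000))
        sets[i].update(f"private_{i}_{offset + k}" for k in range(n_private))
    return sets
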