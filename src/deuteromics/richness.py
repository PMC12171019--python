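"""Power-law modelling of per-taxon sequence-variant richness.

The model relates the number of distinct sequence variants observed for a
taxon (d_obs, unique ORFs) to the taxon's summed abundance A (TPM):

    d_exp = c * A^gamma

fitted by ordinary least squares of log10(d_obs) on log10(A).  The slope
gamma measures how fast unique variants accrue with abundance; the
deviation coefficient delta = d_obs / d_exp quantifies, per taxon, excess
(delta > 1) or deficit (delta < 1) of variants relative to expectation.
The spread of log10(delta) across taxa — visualized with a Gaussian KDE —
compares diversification between environments, and two fitted slopes are
compared with a two-sample z test on their OLS standard errors.

Usage follows the Model/Results pattern::

    model = PowerLawRichnessModel.from_orf_table(table, environment="drum1")
    fit = model.fit()
    print(fit.summary())
    dist = fit.delta_distribution()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ComparisonError, FitError
from .tables_io import OrfTable

__all__ = [
    "TaxonRichnessPoint", "build_points", "PowerLawRichnessModel",
    "PowerLawFit", "DeltaDistribution", "compare_slopes", "compare_spread",
]


@dataclass(frozen=True)
class TaxonRichnessPoint:
    """One taxon's abundance/richness observation in one environment.

    ``A`` is the summed TPM over the taxon's ORFs in scope; ``d_obs`` the
    number of distinct ORF variants observed for the taxon.
    """

    taxon: str
    environment: str
    A: float
    d_obs: int

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"negative abundance for taxon {self.taxon!r}")
        if self.d_obs < 0:
            raise ValueError(f"negative richness for taxon {self.taxon!r}")


def build_points(table: OrfTable, environment: str,
                 gene_scope: set[str] | None = None,
                 samples: Sequence[str] | None = None) -> list[TaxonRichnessPoint]:
    """Aggregate an ORF table into per-taxon (A, d_obs) points.

    ORFs are grouped by species tag; ``d_obs`` counts distinct ORF ids in
    the group and ``A`` sums TPM over the group and the in-scope samples
    (all samples by default).  ``gene_scope`` optionally restricts to
    ORFs whose annotations intersect the given orthogroup set — e.g. a
    nitrogen-cycle gene subset when comparing against reference
    environments.
    """
    scope = list(samples) if samples is not None else list(table.sample_ids)
    for s in scope:
        if s not in table.sample_ids:
            raise KeyError(f"unknown sample {s!r}")
    grouped: dict[str, tuple[set[str], float]] = {}
    for rec in table:
        if gene_scope is not None and not (rec.annotations & gene_scope):
            continue
        tag = rec.species_tag
        ids, total = grouped.setdefault(tag, (set(), 0.0))
        ids.add(rec.orf_id)
        total += sum(rec.tpm.get(s, 0.0) for s in scope)
        grouped[tag] = (ids, total)
    if not grouped:
        warnings.warn("no ORFs left after gene-scope filtering", stacklevel=2)
    return [TaxonRichnessPoint(taxon=tag, environment=environment,
                               A=total, d_obs=len(ids))
            for tag, (ids, total) in grouped.items()]


class PowerLawRichnessModel:
    """OLS model of log10 richness against log10 abundance.

    Points with ``d_obs`` below ``min_dobs`` or non-positive abundance are
    excluded (the logarithm is undefined) and counted in the results.
    """

    def __init__(self, points: Iterable[TaxonRichnessPoint],
                 min_dobs: int = 1) -> None:
        self.points = list(points)
        self.min_dobs = int(min_dobs)
        usable = [p for p in self.points if p.d_obs >= self.min_dobs and p.A > 0]
        self.n_excluded = len(self.points) - len(usable)
        self._usable = usable

    @classmethod
    def from_orf_table(cls, table: OrfTable, environment: str,
                       gene_scope: set[str] | None = None,
                       samples: Sequence[str] | None = None,
                       min_dobs: int = 1) -> "PowerLawRichnessModel":
        return cls(build_points(table, environment, gene_scope, samples),
                   min_dobs=min_dobs)

    def fit(self) -> "PowerLawFit":
        """Fit by OLS in log10–log10 space and return a :class:`PowerLawFit`."""
        if len(self._usable) < 3:
            raise FitError(
                f"need >= 3 usable points, have {len(self._usable)} "
                f"({self.n_excluded} excluded)")
        logA = np.log10([p.A for p in self._usable])
        logd = np.log10([p.d_obs for p in self._usable])
        if np.ptp(logA) == 0:
            raise FitError("zero variance in log10 abundance; slope undefined")
        X = sm.add_constant(logA)
        res = sm.OLS(logd, X).fit()
        env = self._usable[0].environment if self._usable else ""
        return PowerLawFit(
            c=float(10.0 ** res.params[0]),
            gamma=float(res.params[1]),
            se_c_log=float(res.bse[0]),
            se_gamma=float(res.bse[1]),
            r_squared=float(res.rsquared),
            n_points=len(self._usable),
            n_excluded=self.n_excluded,
            residuals=np.asarray(res.resid),
            points=list(self._usable),
            environment=env,
        )


@dataclass
class PowerLawFit:
    """Fitted abundance–richness power law d_exp = c * A^gamma.

    ``c`` is the expected variant count at A = 1; ``gamma`` the log-log
    slope; ``se_c_log`` the standard error of the intercept on the log10
    scale; ``residuals`` are log10(d_obs) - log10(d_exp) for the fitted
    points.
    """

    c: float
    gamma: float
    se_c_log: float
    se_gamma: float
    r_squared: float
    n_points: int
    n_excluded: int
    residuals: np.ndarray
    points: list[TaxonRichnessPoint] = field(default_factory=list)
    environment: str = ""

    def predict(self, A) -> np.ndarray:
        """Expected richness d_exp = c * A^gamma."""
        return self.c * np.power(np.asarray(A, dtype=float), self.gamma)

    def delta_distribution(self, bandwidth: str | float = "scott",
                           grid_size: int = 512) -> "DeltaDistribution":
        """Per-taxon deviation coefficients delta = d_obs / d_exp with KDE.

        Taxa with d_obs = 0 are excluded (log-delta undefined) and
        counted.  The Gaussian KDE of log10(delta) is evaluated on a grid
        spanning the observed range extended by three bandwidths.
        """
        kept = [p for p in self.points if p.d_obs > 0 and p.A > 0]
        n_excluded = len(self.points) - len(kept)
        if len(kept) < 2:
            raise FitError("need >= 2 positive-richness points for deltas")
        deltas = np.array([p.d_obs / self.predict(p.A) for p in kept])
        log_deltas = np.log10(deltas)
        kde = stats.gaussian_kde(log_deltas, bw_method=bandwidth)
        h = kde.factor * log_deltas.std(ddof=1)
        if h == 0:
            h = 1e-3  # degenerate: all deltas identical
        grid = np.linspace(log_deltas.min() - 3 * h, log_deltas.max() + 3 * h,
                           grid_size)
        return DeltaDistribution(
            taxa=[p.taxon for p in kept],
            deltas=deltas, log_deltas=log_deltas,
            grid=grid, density=kde(grid),
            spread=float(log_deltas.std(ddof=0)),
            bandwidth=float(h), n_excluded=n_excluded,
            environment=self.environment)

    def compare_slopes(self, other: "PowerLawFit") -> tuple[float, float]:
        """Two-sample z test of this slope against another fit's slope."""
        return compare_slopes(self.gamma, self.se_gamma,
                              other.gamma, other.se_gamma)

    def summary(self) -> str:
        """Plain-text summary table of the fitted law."""
        lines = [
            "Power-law richness fit: d_exp = c * A^gamma",
            f"  environment : {self.environment or '-'}",
            f"  n points    : {self.n_points}  (excluded: {self.n_excluded})",
            f"  gamma       : {self.gamma:.4f} +/- {self.se_gamma:.4f}",
            f"  c           : {self.c:.4g}  (log10 se {self.se_c_log:.4f})",
            f"  R^2         : {self.r_squared:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "environment": self.environment, "c": self.c, "gamma": self.gamma,
            "se_c_log": self.se_c_log, "se_gamma": self.se_gamma,
            "r_squared": self.r_squared, "n_points": self.n_points,
            "n_excluded": self.n_excluded,
        }


@dataclass
class DeltaDistribution:
    """Distribution of richness deviation coefficients for one fit.

    ``spread`` is the standard deviation of log10(delta); because the
    deltas are computed against the OLS fit of the same points, the mean
    of log10(delta) is zero and the geometric mean of delta is one.
    """

    taxa: list[str]
    deltas: np.ndarray
    log_deltas: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    spread: float
    bandwidth: float
    n_excluded: int
    environment: str = ""

    def compare_spread(self, other: "DeltaDistribution") -> float:
        """Ratio of log10-delta spreads (this / other)."""
        return compare_spread(self, other)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"log10_delta_grid": self.grid,
                             "density": self.density})

    def plot(self, ax=None, **kwargs):
        """Plot the KDE of log10(delta); 0 marks expected richness."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.density,
                label=self.environment or None, **kwargs)
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(r"log$_{10}\,\delta$ (deviation from expected richness)")
        ax.set_ylabel("density")
        if self.environment:
            ax.legend()
        return ax


def compare_slopes(gamma_a: float, se_a: float,
                   gamma_b: float, se_b: float) -> tuple[float, float]:
    """Two-sample z test for equality of two power-law slopes.

    z = (gamma_a - gamma_b) / sqrt(se_a^2 + se_b^2); the two-sided
    p-value comes from the standard normal.
    """
    joint = float(np.hypot(se_a, se_b))
    if joint <= 0:
        raise ComparisonError("both standard errors are zero")
    z = (gamma_a - gamma_b) / joint
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_spread(dist_a: DeltaDistribution, dist_b: DeltaDistribution) -> float:
    """Ratio of log10-delta spreads; > 1 means ``dist_a`` is wider."""
    if dist_b.spread <= 0:
        raise ComparisonError("reference distribution has zero spread")
    return dist_a.spread / dist_b.spread
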