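"""Calling significantly mutated domains (SMDs).

Per (Pfam family, cancer type) the accumulated mutation count is normalised
by the family's cumulative length, giving a relative mutation frequency
``p`` (mutations per coding nucleotide by default).  Treating ``p`` as a
Bernoulli success probability, its signal-to-noise ratio

    z = p / sqrt(p * (1 - p))

is the normalised score.  The population of z scores within one cancer type
is then modelled as a two-group mixture: a dominant empirical null (fitted
from the central bulk of the histogram by central matching, after Efron's
microarray work) plus a sparse non-null tail.  The local false discovery
rate

    fdr(z) = pi0 * f0(z) / f(z)

is the posterior probability of the null given z, with f the smoothed
marginal density (Poisson regression of histogram counts on a B-spline
basis) and f0 the fitted normal null.  Families with fdr(z) < 0.1 are
called significantly mutated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import norm

from smdtools.mutmap import DomainMutationCount

logger = logging.getLogger(__name__)

DEFAULT_LOCFDR_THRESHOLD = 0.1
DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class SmdResult:
    """Score and significance call for one (Pfam family, cancer type)."""

    domain_family: str
    primary_site: str
    accumulated_count: int
    cumulative_length_aa: int
    p: float
    z: float
    locfdr: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.z <= 0:
            raise ValueError(f"z must be positive, got {self.z}")
        if not 0.0 <= self.locfdr <= 1.0:
            raise ValueError(f"locfdr must lie in [0, 1], got {self.locfdr}")


@dataclass(frozen=True)
class _MarginalFit:
    """Smoothed marginal density: Poisson-GLM spline over histogram bins."""

    knots: np.ndarray
    coeffs: np.ndarray
    degree: int
    z_min: float
    z_max: float
    n: int
    bin_width: float

    def log_density(self, z: np.ndarray) -> np.ndarray:
        zc = np.clip(np.asarray(z, dtype=float), self.z_min, self.z_max)
        eta = BSpline(self.knots, self.coeffs, self.degree)(zc)
        return eta - math.log(self.n * self.bin_width)

    def density(self, z: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(z))


@dataclass(frozen=True)
class NullFit:
    """Empirical null for one z population.

    ``delta``/``sigma`` are the null centre and spread, ``pi0`` the null
    proportion.  ``theoretical`` marks the N(0, 1), pi0 = 1 fallback used
    for small or degenerate samples.
    """

    delta: float
    sigma: float
    pi0: float
    n_bins: int
    spline_df: int
    theoretical: bool = False
    marginal: _MarginalFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in (0, 1]")

    def null_density(self, z: np.ndarray) -> np.ndarray:
        return norm.pdf(np.asarray(z, dtype=float), self.delta, self.sigma)


def relative_frequency(
    c: DomainMutationCount,
    basis: str = "nt",
    eps: float = DEFAULT_EPS,
    clamp_log: list | None = None,
) -> float:
    """Relative mutation frequency of a family in a cancer type.

    With the default nucleotide basis, ``p = count / (3 × cumulative
    amino-acid length)`` — mutations are genomic events, so the denominator
    counts coding nucleotides.  ``basis="aa"`` divides by the amino-acid
    length instead.  The result is clamped into the open interval
    ``[eps, 1 - eps]`` (the z score is undefined at 0 and 1); clamp events
    are appended to ``clamp_log`` when given.
    """
    if c.cumulative_length_aa <= 0:
        raise ValueError("cumulative_length_aa must be positive")
    if basis == "nt":
        denom = 3 * c.cumulative_length_aa
    elif basis == "aa":
        denom = c.cumulative_length_aa
    else:
        raise ValueError(f"unknown basis {basis!r}; use 'nt' or 'aa'")
    p = c.accumulated_count / denom
    clamped = min(max(p, eps), 1.0 - eps)
    if clamped != p and clamp_log is not None:
        clamp_log.append((c.domain_family, c.primary_site, p, clamped))
    return clamped


def zscore(p: float) -> float:
    """Bernoulli signal-to-noise score ``z = p / sqrt(p (1 - p))``,
    equivalently ``sqrt(p / (1 - p))``; strictly increasing in p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in the open interval (0, 1), got {p}")
    return p / math.sqrt(p * (1.0 - p))


def _spline_basis(n_df: int, z_min: float, z_max: float, degree: int = 3) -> np.ndarray:
    """Clamped B-spline knot vector giving exactly ``n_df`` basis functions
    over [z_min, z_max]."""
    n_internal = n_df - degree - 1
    if n_internal < 0:
        raise ValueError(f"spline_df must be >= {degree + 1}")
    internal = np.linspace(z_min, z_max, n_internal + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, z_min), internal, np.full(degree + 1, z_max)]
    )


def fit_empirical_null(
    z: Sequence[float],
    n_bins: int = 120,
    spline_df: int = 7,
    central_mass: float = 0.5,
    min_n: int = 200,
    pi0_cap: float = 1.0,
) -> NullFit:
    """Fit the empirical null of a z population by central matching.

    The marginal density is fitted by Poisson regression of histogram
    counts (``n_bins`` equal-width bins) on a ``spline_df``-df cubic
    B-spline basis.  A quadratic is then fitted to the log smoothed counts
    over the bins holding the central ``central_mass`` of the data; its
    curvature and slope give the null spread and centre, and pi0 comes from
    the ratio of the fitted null to the marginal at the null mode, capped
    at ``pi0_cap``.

    Samples smaller than ``min_n``, or with degenerate spread, fall back to
    the theoretical N(0, 1) null with pi0 = 1 (with a warning).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < min_n:
        warnings.warn(
            f"only {n} scores (< {min_n}); using the theoretical N(0,1) null",
            stacklevel=2,
        )
        marginal = _fit_marginal(z, n_bins, spline_df) if n and np.ptp(z) > 0 else None
        return NullFit(0.0, 1.0, 1.0, n_bins, spline_df, theoretical=True,
                       marginal=marginal)
    if np.ptp(z) == 0:
        warnings.warn("degenerate z sample (all equal); using the theoretical "
                      "N(0,1) null", stacklevel=2)
        return NullFit(0.0, 1.0, 1.0, n_bins, spline_df, theoretical=True)

    marginal = _fit_marginal(z, n_bins, spline_df)
    centers = np.linspace(
        marginal.z_min + marginal.bin_width / 2,
        marginal.z_max - marginal.bin_width / 2,
        n_bins,
    )
    eta = BSpline(marginal.knots, marginal.coeffs, marginal.degree)(centers)

    tail = (1.0 - central_mass) / 2
    lo, hi = np.quantile(z, [tail, 1.0 - tail])
    window = (centers >= lo) & (centers <= hi)
    if window.sum() < 3:
        window = np.ones_like(centers, dtype=bool)
    c2, c1, c0 = np.polyfit(centers[window], eta[window], 2)
    if c2 >= 0:
        warnings.warn("central log-density is not concave; using the "
                      "theoretical N(0,1) null", stacklevel=2)
        return NullFit(0.0, 1.0, 1.0, n_bins, spline_df, theoretical=True,
                       marginal=marginal)
    sigma = math.sqrt(-1.0 / (2.0 * c2))
    delta = c1 * sigma**2
    log_peak = c0 + delta**2 / (2.0 * sigma**2)  # log expected counts at the mode
    pi0 = math.exp(log_peak) * sigma * math.sqrt(2.0 * math.pi) / (n * marginal.bin_width)
    pi0 = min(max(pi0, 1e-12), pi0_cap)
    return NullFit(delta, sigma, pi0, n_bins, spline_df, marginal=marginal)


def _fit_marginal(z: np.ndarray, n_bins: int, spline_df: int) -> _MarginalFit:
    z_min, z_max = float(z.min()), float(z.max())
    edges = np.linspace(z_min, z_max, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    knots = _spline_basis(spline_df, z_min, z_max)
    design = BSpline.design_matrix(centers, knots, 3).toarray()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-separation chatter on sparse bins
        glm = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    return _MarginalFit(
        knots=knots,
        coeffs=np.asarray(glm.params),
        degree=3,
        z_min=z_min,
        z_max=z_max,
        n=int(z.size),
        bin_width=float(edges[1] - edges[0]),
    )


def locfdr_values(z: Sequence[float], fit: NullFit) -> np.ndarray:
    """Local false discovery rate ``pi0 * f0(z) / f(z)`` per score,
    truncated into [0, 1].

    Without a fitted marginal (degenerate input) every score receives the
    conservative value 1."""
    z = np.asarray(z, dtype=float)
    if fit.marginal is None:
        return np.ones_like(z)
    f = fit.marginal.density(z)
    f0 = fit.null_density(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(f > 0, fit.pi0 * f0 / f, 1.0)
    return np.clip(fdr, 0.0, 1.0)


def call_smds(
    results: Iterable[SmdResult],
    threshold: float = DEFAULT_LOCFDR_THRESHOLD,
) -> list[SmdResult]:
    """The significantly mutated subset: locfdr strictly below ``threshold``
    (a result at exactly the threshold is not called)."""
    called = []
    for r in results:
        if r.locfdr < threshold:
            called.append(
                r if r.significant
                else SmdResult(r.domain_family, r.primary_site, r.accumulated_count,
                               r.cumulative_length_aa, r.p, r.z, r.locfdr, True)
            )
    return called


def top_k(results: Iterable[SmdResult], k: int = 10) -> list[SmdResult]:
    """First ``k`` results by ascending locfdr; ties broken by higher
    accumulated count, then by family accession text."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        results,
        key=lambda r: (r.locfdr, -r.accumulated_count, r.domain_family),
    )
    return ranked[:k]


def heatmap_matrix(
    results: Iterable[SmdResult],
    threshold: float = DEFAULT_LOCFDR_THRESHOLD,
    sentinel: float = 1.0,
) -> pd.DataFrame:
    """Family × cancer-type matrix of locfdr values.

    Rows are the union of families called significant (flagged, or under
    ``threshold`` when no result in the collection is flagged) in at least
    one cancer type; a family with no score in some type gets the
    ``sentinel`` (the uninformative locfdr of 1).  Rows and columns are
    sorted for deterministic output; clustering the matrix is left to the
    caller.
    """
    results = list(results)
    sites = sorted({r.primary_site for r in results})
    if any(r.significant for r in results):
        smd_families = sorted({r.domain_family for r in results if r.significant})
    else:
        smd_families = sorted({r.domain_family for r in results if r.locfdr < threshold})
    mat = pd.DataFrame(sentinel, index=smd_families, columns=sites, dtype=float)
    for r in results:
        if r.domain_family in mat.index:
            mat.loc[r.domain_family, r.primary_site] = r.locfdr
    mat.index.name = "domain_family"
    return mat


# ---------------------------------------------------------------------------
# Model / Results interface

class SmdModel:
    """Two-group empirical-null model over per-family mutation counts.

    Parameters
    ----------
    counts
        DataFrame with columns ``domain_family``, ``primary_site``,
        ``accumulated_count``, ``cumulative_length_aa`` (one row per family
        and cancer type), or use :meth:`from_counts`.
    basis
        ``"nt"`` (mutations per coding nucleotide, default) or ``"aa"``.
    include_zero_counts
        Keep unmutated families in the score population (default), so the
        null is dominated by weakly mutated families; set False to drop
        them.
    eps, n_bins, spline_df, central_mass, min_null_n, pi0_cap
        Numerical settings passed through to the frequency clamp and
        :func:`fit_empirical_null`.

    Each cancer type is fitted independently: its families form one z
    population with its own empirical null.
    """

    _REQUIRED = ("domain_family", "primary_site", "accumulated_count",
                 "cumulative_length_aa")

    def __init__(
        self,
        counts: pd.DataFrame,
        *,
        basis: str = "nt",
        eps: float = DEFAULT_EPS,
        include_zero_counts: bool = True,
        n_bins: int = 120,
        spline_df: int = 7,
        central_mass: float = 0.5,
        min_null_n: int = 200,
        pi0_cap: float = 1.0,
    ) -> None:
        missing = [c for c in self._REQUIRED if c not in counts.columns]
        if missing:
            raise ValueError(f"counts frame is missing columns {missing}")
        self.counts = counts.reset_index(drop=True)
        self.basis = basis
        self.eps = eps
        self.include_zero_counts = include_zero_counts
        self.n_bins = n_bins
        self.spline_df = spline_df
        self.central_mass = central_mass
        self.min_null_n = min_null_n
        self.pi0_cap = pi0_cap

    @classmethod
    def from_counts(cls, counts: Iterable[DomainMutationCount], **kwargs) -> "SmdModel":
        frame = pd.DataFrame(
            [
                (c.domain_family, c.primary_site, c.accumulated_count,
                 c.cumulative_length_aa)
                for c in counts
            ],
            columns=list(cls._REQUIRED),
        )
        return cls(frame, **kwargs)

    def fit(self, locfdr_threshold: float = DEFAULT_LOCFDR_THRESHOLD) -> "SmdResults":
        """Fit the per-cancer-type empirical nulls and score every family."""
        frame = self.counts
        if not self.include_zero_counts:
            frame = frame[frame["accumulated_count"] > 0]
        clamp_log: list = []
        rows: list[SmdResult] = []
        null_fits: dict[str, NullFit] = {}
        for site, grp in frame.groupby("primary_site", sort=True):
            p = np.array(
                [
                    relative_frequency(
                        DomainMutationCount(r.domain_family, site,
                                            int(r.accumulated_count),
                                            int(r.cumulative_length_aa), 1),
                        basis=self.basis, eps=self.eps, clamp_log=clamp_log,
                    )
                    for r in grp.itertuples(index=False)
                ]
            )
            zz = np.array([zscore(v) for v in p])
            fit = fit_empirical_null(
                zz, n_bins=self.n_bins, spline_df=self.spline_df,
                central_mass=self.central_mass, min_n=self.min_null_n,
                pi0_cap=self.pi0_cap,
            )
            null_fits[site] = fit
            fdr = locfdr_values(zz, fit)
            # One-sided call: a low locfdr on the *deficient* side (z below
            # the null centre, e.g. unmutated families at the clamp) is not
            # mutation enrichment and is never flagged.
            for r, pi, zi, qi in zip(grp.itertuples(index=False), p, zz, fdr):
                rows.append(
                    SmdResult(
                        domain_family=r.domain_family,
                        primary_site=site,
                        accumulated_count=int(r.accumulated_count),
                        cumulative_length_aa=int(r.cumulative_length_aa),
                        p=float(pi),
                        z=float(zi),
                        locfdr=float(qi),
                        significant=bool(qi < locfdr_threshold and zi >= fit.delta),
                    )
                )
        return SmdResults(self, rows, null_fits, locfdr_threshold, clamp_log)


class SmdResults:
    """Fitted SMD results: per-family scores, per-site null fits and the
    significance calls, with tabular accessors and writers."""

    def __init__(
        self,
        model: SmdModel,
        results: list[SmdResult],
        null_fits: dict[str, NullFit],
        threshold: float,
        clamp_log: list,
    ) -> None:
        self.model = model
        self.results = results
        self.null_fits = null_fits
        self.threshold = threshold
        self.clamp_log = clamp_log

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.domain_family, r.primary_site, r.accumulated_count,
                 r.cumulative_length_aa, r.p, r.z, r.locfdr, r.significant)
                for r in self.results
            ],
            columns=["domain_family", "primary_site", "accumulated_count",
                     "cumulative_length_aa", "p", "z", "locfdr", "significant"],
        )

    def significant(self) -> list[SmdResult]:
        """Flagged calls: locfdr below the threshold on the enriched side
        (z at or above the fitted null centre)."""
        return [r for r in self.results if r.significant]

    def top(self, k: int = 10, site: str | None = None) -> list[SmdResult]:
        """Top-k by ascending locfdr among enrichment-side results (z at or
        above the site's fitted null centre), so mutation-deficient
        families never outrank enriched ones."""
        pool = [
            r for r in self.results
            if (site is None or r.primary_site == site)
            and r.z >= self.null_fits[r.primary_site].delta
        ]
        return top_k(pool, k)

    def heatmap_matrix(self) -> pd.DataFrame:
        return heatmap_matrix(self.results, self.threshold)

    def summary(self) -> str:
        """Plain-text summary: one line per cancer type with its null fit
        and call count."""
        lines = [
            "Significantly mutated domains (empirical-null locfdr "
            f"< {self.threshold:g}, basis={self.model.basis})",
            f"{'site':<20}{'families':>10}{'delta':>10}{'sigma':>10}"
            f"{'pi0':>8}{'called':>8}",
        ]
        by_site: dict[str, list[SmdResult]] = {}
        for r in self.results:
            by_site.setdefault(r.primary_site, []).append(r)
        for site in sorted(by_site):
            fit = self.null_fits[site]
            called = sum(r.significant for r in by_site[site])
            tag = "*" if fit.theoretical else ""
            lines.append(
                f"{site:<20}{len(by_site[site]):>10}{fit.delta:>10.3f}"
                f"{fit.sigma:>10.3f}{fit.pi0:>8.3f}{called:>8}{tag}"
            )
        if any(f.theoretical for f in self.null_fits.values()):
            lines.append("* theoretical N(0,1) null (small or degenerate sample)")
        if self.clamp_log:
            lines.append(f"frequency clamps applied: {len(self.clamp_log)}")
        return "\n".join(lines)

    def to_tsv(self, results_path: str, topk_path: str | None = None,
               matrix_path: str | None = None, k: int = 10) -> None:
        self.frame.to_csv(results_path, sep="\t", index=False)
        if topk_path is not None:
            rows = []
            for site in sorted({r.primary_site for r in self.results}):
                for rank, r in enumerate(self.top(k, site=site), start=1):
                    rows.append((site, rank, r.domain_family, r.accumulated_count,
                                 r.locfdr))
            pd.DataFrame(
                rows, columns=["primary_site", "rank", "domain_family",
                               "accumulated_count", "locfdr"],
            ).to_csv(topk_path, sep="\t", index=False)
        if matrix_path is not None:
            self.heatmap_matrix().to_csv(matrix_path, sep="\t")
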