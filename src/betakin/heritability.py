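"""Sibling variance-component heritability with a permutation null.

Model: phenotype y = mu + g + e with additive genetic and residual
variances sigma2_g, sigma2_e; the covariance is block diagonal per family,

    Sigma_fam = sigma2_g * R + sigma2_e * I,

where R has ones on the diagonal and the full-sib coefficient of
relationship 0.5 between siblings. Heritability is
h2 = sigma2_g / (sigma2_g + sigma2_e).

The Gaussian likelihood is maximized by profiling: for a given h2 the
per-unit-variance family covariance is C = (1 - 0.5 h2) I + 0.5 h2 J
(J the all-ones block), whose determinant and inverse are closed-form, so
the intercept and the total variance have closed-form ML solutions and the
profile log-likelihood is a cheap one-dimensional function of h2 on [0, 1].
This makes a 6,000-permutation null (family labels reshuffled uniformly,
original sibships allowed to recur) affordable. Significance is the
one-tailed exceedance fraction k / n_perm, with ties counted as
exceedances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .pedigree import Pedigree

__all__ = [
    "HeritabilityResult",
    "PermutationResult",
    "TransformRecord",
    "prepare_phenotype",
    "fit_variance_components",
    "permutation_test",
    "bonferroni",
    "cohens_d",
    "run_heritability_battery",
    "BATTERY_PHENOTYPES",
]

_H2_GRID = np.linspace(0.0, 1.0, 1001)  # 1e-3 resolution


@dataclass(frozen=True)
class TransformRecord:
    requested: str
    applied: str


@dataclass(frozen=True)
class HeritabilityResult:
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    n_subjects: int
    n_families: int
    transform_applied: str = "none"
    degenerate: bool = False

    @property
    def total_variance(self) -> float:
        return self.sigma2_g + self.sigma2_e


@dataclass(frozen=True)
class PermutationResult:
    """Exceedance count k over n_perm family-label permutations.

    The one-tailed p-value is k / n_perm (ties counted as exceedances, so
    an observed h2 of zero yields k = n_perm and p = 1).
    """

    n_perm: int
    k: int
    seed: int = 0
    observed_h2: float = math.nan

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n_perm:
            raise ValueError("k must lie in [0, n_perm]")

    @property
    def p(self) -> float:
        return self.k / self.n_perm


def prepare_phenotype(values: pd.Series | np.ndarray,
                      transform: str = "flip") -> tuple[pd.Series, TransformRecord]:
    """Bring a phenotype into the form the variance-component fit expects.

    ``flip``: phenotypes whose median is negative are multiplied by -1
    (the nonnegativity convention of pedigree variance-component tools);
    a mixed-sign phenotype with near-zero median is min-shifted instead,
    with a warning. ``invnorm``: rank-based inverse-normal transform with
    Blom offsets, Phi^-1((rank - 3/8) / (n + 1/4)). ``none``: unchanged.
    """
    series = pd.Series(values).astype(float)
    vals = series.dropna()
    if vals.size < 4:
        raise ValueError(f"need >= 4 non-missing values, got {vals.size}")
    if transform == "none":
        return series, TransformRecord("none", "none")
    if transform == "flip":
        med = float(vals.median())
        if abs(med) < 1e-12 and (vals > 0).any() and (vals < 0).any():
            warnings.warn("mixed-sign phenotype with near-zero median; "
                          "applying min-shift instead of sign flip")
            return series - vals.min(), TransformRecord("flip", "min_shift")
        if med < 0:
            return -series, TransformRecord("flip", "sign_flip")
        return series, TransformRecord("flip", "none")
    if transform == "invnorm":
        ranks = spstats.rankdata(vals.to_numpy())
        scores = spstats.norm.ppf((ranks - 3.0 / 8.0) / (vals.size + 0.25))
        out = series.copy()
        out.loc[vals.index] = scores
        return out, TransformRecord("invnorm", "inverse_normal")
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# profile likelihood machinery


def _size_aggregates(y_blocks: np.ndarray, sizes: np.ndarray):
    """Per-family-size sufficient statistics of block-ordered phenotypes.

    ``y_blocks``: (R, n) rows of phenotype vectors, family blocks
    contiguous with lengths ``sizes``. For each distinct family size m the
    profile likelihood needs only the number of families F_m, the summed
    family totals S1_m, the summed squared totals T2_m and the summed
    within-family sums of squares Q_m (each per row).
    """
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    s = np.add.reduceat(y_blocks, starts, axis=1)
    q = np.add.reduceat(y_blocks ** 2, starts, axis=1)
    groups = {}
    for m in np.unique(sizes):
        idx = np.flatnonzero(sizes == m)
        groups[int(m)] = (
            idx.size,
            s[:, idx].sum(axis=1),
            (s[:, idx] ** 2).sum(axis=1),
            q[:, idx].sum(axis=1),
        )
    return groups


def _profile_loglik(groups, n: int, h2: np.ndarray, reml: bool = False):
    """Profile log-likelihood over an h2 grid for each phenotype row.

    Returns ``(ll, mu, vp)`` with shapes (R, G): the intercept and total
    variance are profiled out in closed form for each h2.
    """
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    a = 1.0 - 0.5 * h2  # diagonal minus off-diagonal of C
    b = 0.5 * h2
    A = np.zeros_like(h2)
    logdet = np.zeros_like(h2)
    U = 0.0
    for m, (fm, s1, _, _) in groups.items():
        denom = a + m * b
        A += fm * m / denom
        logdet += fm * ((m - 1) * np.log(a) + np.log(denom))
        U = U + s1[:, None] / denom[None, :]
    mu = U / A[None, :]
    Q = 0.0
    for m, (fm, s1, t2, qs) in groups.items():
        denom = a + m * b
        r_sq = qs[:, None] - 2.0 * mu * s1[:, None] + m * mu ** 2 * fm
        r_sum_sq = (t2[:, None] - 2.0 * m * mu * s1[:, None]
                    + m ** 2 * mu ** 2 * fm)
        Q = Q + (r_sq - (b / denom)[None, :] * r_sum_sq) / a[None, :]
    if reml:
        dof = n - 1
        vp = Q / dof
        ll = -0.5 * (dof * math.log(2 * math.pi) + dof * np.log(vp)
                     + logdet[None, :] + np.log(A)[None, :] + dof)
    else:
        vp = Q / n
        ll = -0.5 * (n * math.log(2 * math.pi) + n * np.log(vp)
                     + logdet[None, :] + n)
    return ll, mu, vp


def _block_order(values: pd.Series, ped: Pedigree):
    """Non-missing phenotype values in family-block order."""
    vals = values.dropna()
    ids = [s for s in ped.subjects if s in vals.index]
    order, sizes = ped.block_index(ids)
    y = vals.loc[ids].to_numpy()[order]
    return y, sizes


def _h2_argmax(ll: np.ndarray, grid: np.ndarray, refine: bool = True) -> np.ndarray:
    """Grid argmax with optional parabolic refinement (clipped to [0, 1])."""
    idx = np.argmax(ll, axis=1)
    h2 = grid[idx]
    if not refine:
        return h2
    h2 = h2.astype(float).copy()
    step = grid[1] - grid[0]
    interior = (idx > 0) & (idx < grid.size - 1)
    for r in np.flatnonzero(interior):
        i = idx[r]
        y0, y1, y2 = ll[r, i - 1], ll[r, i], ll[r, i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            h2[r] = float(np.clip(grid[i] + 0.5 * step * (y0 - y2) / denom, 0.0, 1.0))
    return h2


def fit_variance_components(values: pd.Series | np.ndarray, ped: Pedigree,
                            reml: bool = False,
                            transform_applied: str = "none") -> HeritabilityResult:
    """Maximum-likelihood variance components for one phenotype.

    ``values`` is a Series indexed by subject id (missing values drop the
    subject) or an array aligned with ``ped.subjects``. ML is the default
    (matching standard pedigree variance-component software); set
    ``reml=True`` for the restricted likelihood.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float), index=ped.subjects)
    y, sizes = _block_order(values, ped)
    n = y.size
    if n < 4:
        raise ValueError(f"need >= 4 non-missing subjects, got {n}")
    if np.var(y) == 0:
        return HeritabilityResult(sigma2_g=0.0, sigma2_e=0.0, h2=math.nan,
                                  loglik=math.nan, n_subjects=n,
                                  n_families=sizes.size,
                                  transform_applied=transform_applied,
                                  degenerate=True)
    groups = _size_aggregates(y[None, :], sizes)
    ll, _, _ = _profile_loglik(groups, n, _H2_GRID, reml=reml)
    h2 = float(_h2_argmax(ll, _H2_GRID, refine=True)[0])
    ll_h, _, vp_h = _profile_loglik(groups, n, np.array([h2]), reml=reml)
    vp = float(vp_h[0, 0])
    return HeritabilityResult(
        sigma2_g=h2 * vp, sigma2_e=(1.0 - h2) * vp, h2=h2,
        loglik=float(ll_h[0, 0]), n_subjects=n, n_families=sizes.size,
        transform_applied=transform_applied,
    )


def permutation_test(values: pd.Series | np.ndarray, ped: Pedigree,
                     n_perm: int = 6000, seed: int = 0,
                     reml: bool = False,
                     chunk: int = 1000) -> PermutationResult:
    """One-tailed permutation test of h2 > 0 by family-label reshuffling.

    Subjects are reassigned to the fixed family blocks uniformly at random
    (family sizes preserved; nothing prevents an original sibship from
    recurring, which if anything is conservative). ``k`` counts
    permutations whose fitted h2 is >= the observed h2, ties included, and
    p = k / n_perm. The observed statistic uses the same grid-resolution
    estimator as the permuted ones so that ties are exact.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float), index=ped.subjects)
    y, sizes = _block_order(values, ped)
    n = y.size
    groups = _size_aggregates(y[None, :], sizes)
    ll_obs, _, _ = _profile_loglik(groups, n, _H2_GRID, reml=reml)
    h2_obs = float(_h2_argmax(ll_obs, _H2_GRID, refine=False)[0])

    rng = np.random.default_rng(seed)
    k = 0
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        perms = np.empty((r, n), dtype=np.intp)
        for i in range(r):
            perms[i] = rng.permutation(n)
        groups_p = _size_aggregates(y[perms], sizes)
        ll, _, _ = _profile_loglik(groups_p, n, _H2_GRID, reml=reml)
        h2_perm = _h2_argmax(ll, _H2_GRID, refine=False)
        k += int(np.sum(h2_perm >= h2_obs))
        done += r
    return PermutationResult(n_perm=n_perm, k=k, seed=seed, observed_h2=h2_obs)


def bonferroni(p_values, n_tests: int = 30, alpha: float = 0.05):
    """Bonferroni control at family-wise level ``alpha`` over ``n_tests``.

    Returns ``(significant, adjusted)``: significant iff p < alpha/n_tests;
    adjusted p = min(1, p * n_tests).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / n_tests, np.minimum(1.0, p * n_tests)


def cohens_d(values) -> float:
    """Single-group effect size D = M / S (sample mean over sample SD)."""
    vals = pd.Series(values).dropna().to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: Cohen's d undefined")
    return float(vals.mean() / sd)


#: The 15 per-hemisphere phenotypes of the full battery.
BATTERY_PHENOTYPES = (
    "peak_beta_frequency", "peak_beta_power", "total_beta_power",
    "aperiodic_exponent", "aperiodic_offset",
    "duration_mean", "duration_median", "duration_sd", "duration_robust_max",
    "amplitude_mean", "amplitude_median", "amplitude_sd", "amplitude_robust_max",
    "event_rate", "dispersion",
)


def run_heritability_battery(
    table: pd.DataFrame,
    ped: Pedigree,
    n_perm: int = 6000,
    seed: int = 0,
    transform: str = "flip",
    n_tests: int | None = None,
    alpha: float = 0.05,
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Heritability, permutation p, Bonferroni flag and effect size for every
    phenotype column.

    ``table`` is subjects x phenotypes (index = subject ids matching the
    pedigree). ``phenotypes`` restricts/validates the column set; missing
    requested columns raise with their names. ``n_tests`` defaults to the
    number of phenotypes analysed (30 for the full two-hemisphere battery).
    Effect sizes are computed on the sign-flipped (pre-inverse-normal)
    values, i.e. on the feature scale.
    """
    cols = list(table.columns) if phenotypes is None else list(phenotypes)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype columns missing from table: {missing}")
    if n_tests is None:
        n_tests = len(cols)
    rows = []
    for j, col in enumerate(cols):
        pheno_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(j,))
                         .generate_state(1)[0] % (2 ** 31))
        flipped, _ = prepare_phenotype(table[col], transform="flip")
        prepared, record = prepare_phenotype(table[col], transform=transform)
        fit = fit_variance_components(prepared, ped,
                                      transform_applied=record.applied)
        if fit.degenerate:
            rows.append({"phenotype": col, "transform": record.applied,
                         "h2": math.nan, "k": n_perm, "p": 1.0,
                         "cohens_d": math.nan, "n_subjects": fit.n_subjects,
                         "degenerate": True})
            continue
        perm = permutation_test(prepared, ped, n_perm=n_perm, seed=pheno_seed)
        rows.append({"phenotype": col, "transform": record.applied,
                     "h2": fit.h2, "k": perm.k, "p": perm.p,
                     "cohens_d": cohens_d(flipped),
                     "n_subjects": fit.n_subjects, "degenerate": False})
    out = pd.DataFrame(rows)
    sig, adj = bonferroni(out["p"].to_numpy(), n_tests=n_tests, alpha=alpha)
    out["p_bonferroni"] = adj
    out["significant"] = sig
    return out
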