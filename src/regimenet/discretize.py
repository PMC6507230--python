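"""Per-gene Gaussian-mixture discretization of expression into regimes.

Each gene's cross-sample expression profile is fit with univariate
Gaussian mixtures for k = 1..k_max components; the Bayesian Information
Criterion selects k (smaller k wins ties), components are sorted by
ascending mean, and every sample is hard-assigned to its maximum-
posterior component. Regime 0 is always the lowest-mean (low-expression)
regime. Missing samples carry the sentinel code -1.

EM settings: 5 restarts with k-means++ initialization, log-likelihood
tolerance 1e-6, at most 500 iterations, and a variance floor of 1e-6
times the gene's total variance to keep components non-singular. The
BIC parameter count for k components is 3k - 1 (k-1 weights, k means,
k variances), so the k = 1 BIC reduces to the closed-form single
Gaussian -2 logL + 2 ln n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .io import ExpressionMatrix

MISSING_CODE = -1

EM_N_RESTARTS = 5
EM_TOL = 1e-6
EM_MAX_ITER = 500
VARIANCE_FLOOR_FRACTION = 1e-6
MIN_VALUES_PER_GENE = 10


class DiscretizationError(ValueError):
    pass


@dataclass
class RegimeProfile:
    """Fitted mixture and regime assignment for one gene.

    Components are sorted by ascending mean so label 0 is the
    low-expression regime. ``codes`` covers only the non-missing
    samples the fit saw, in their original order.
    """

    gene_id: str
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic_by_k: dict[int, float]
    codes: np.ndarray  # per non-missing sample, in {0..k-1}
    sample_ids: list[str]  # non-missing samples, matching codes

    def __post_init__(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-9
        assert np.all(np.diff(self.means) >= 0)

    @property
    def occupancy(self) -> np.ndarray:
        """Samples per regime; sums to the number of non-missing samples."""
        return np.bincount(self.codes, minlength=self.k)


@dataclass
class RegimeMatrix:
    """Discretized transcriptome: integer regime codes, genes x samples.

    ``codes`` uses -1 for samples missing a gene's measurement and for
    genes whose fit failed (listed in ``failed_genes``).
    """

    codes: pd.DataFrame  # int, genes x samples, -1 = missing
    profiles: dict[str, RegimeProfile]
    k_max: int
    failed_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    def k_of(self, gene: str) -> int:
        return self.profiles[gene].k

    def multimodal_genes(self) -> list[str]:
        return [g for g, p in self.profiles.items() if p.k >= 2]

    @classmethod
    def from_codes(cls, codes: pd.DataFrame) -> "RegimeMatrix":
        """Build a RegimeMatrix from known integer regime codes.

        Used when regime labels come from outside the GMM fit (e.g. a
        simulator's ground truth). Mixture metadata is filled with the
        empirical per-regime moments.
        """
        profiles: dict[str, RegimeProfile] = {}
        for gene in codes.index:
            row = codes.loc[gene].to_numpy()
            obs = row != MISSING_CODE
            vals = row[obs].astype(int)
            k = int(vals.max()) + 1 if vals.size else 1
            occ = np.bincount(vals, minlength=k).astype(float)
            w = occ / occ.sum() if occ.sum() else np.ones(k) / k
            profiles[gene] = RegimeProfile(
                gene_id=str(gene),
                k=k,
                weights=w,
                means=np.arange(k, dtype=float),
                variances=np.ones(k),
                bic_by_k={},
                codes=vals,
                sample_ids=[str(s) for s in codes.columns[obs]],
            )
        return cls(codes=codes.astype(int), profiles=profiles,
                   k_max=max((p.k for p in profiles.values()), default=1))


def _subseed(seed: int, gene_index: int) -> int:
    """Reproducible per-gene sub-seed, independent of fit order."""
    return int(np.random.SeedSequence([seed, gene_index]).generate_state(1)[0] % (2**31))


def fit_gene_mixture(
    values: np.ndarray,
    k_max: int,
    seed: int,
    gene_id: str = "",
    sample_ids: Optional[list[str]] = None,
) -> RegimeProfile:
    """Fit 1..k_max-component Gaussian mixtures to one gene and pick k by BIC.

    Ties in BIC go to the smaller k. Samples are hard-assigned to the
    maximum-posterior component; posterior ties go to the lower-mean
    component. A zero-variance profile yields a k = 1 fit rather than an
    error; fewer than 10 observed values is an error.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    x = values[obs]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(values))]
    kept_ids = [s for s, o in zip(sample_ids, obs) if o]
    n = x.size
    if n < MIN_VALUES_PER_GENE:
        raise DiscretizationError(
            f"gene {gene_id!r}: {n} observed values < {MIN_VALUES_PER_GENE}"
        )
    if k_max < 1:
        raise DiscretizationError("k_max must be >= 1")

    total_var = float(np.var(x))
    if total_var == 0.0:
        return RegimeProfile(
            gene_id=gene_id, k=1,
            weights=np.array([1.0]), means=np.array([float(x[0])]),
            variances=np.array([0.0]),
            bic_by_k={1: -math.inf},
            codes=np.zeros(n, dtype=int), sample_ids=kept_ids,
        )

    reg = VARIANCE_FLOOR_FRACTION * total_var
    X = x[:, None]
    fits: dict[int, GaussianMixture] = {}
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=EM_N_RESTARTS,
            init_params="k-means++",
            tol=EM_TOL,
            max_iter=EM_MAX_ITER,
            reg_covar=reg,
            random_state=seed,
        )
        with warnings.catch_warnings():
            # a restart hitting max_iter is acceptable: BIC compares the
            # best restart per k, and the tight tol makes this rare
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gm.fit(X)
        fits[k] = gm
        bic_by_k[k] = float(gm.bic(X))
    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    gm = fits[best_k]

    order = np.argsort(gm.means_[:, 0], kind="stable")
    w = gm.weights_[order]
    mu = gm.means_[order, 0]
    var = gm.covariances_[order, 0, 0]
    # hard assignment by max posterior over mean-sorted components;
    # argmax resolves ties toward the lower-mean component
    log_resp = np.log(w)[None, :] + norm.logpdf(x[:, None], mu[None, :], np.sqrt(var)[None, :])
    codes = np.argmax(log_resp, axis=1)
    return RegimeProfile(
        gene_id=gene_id, k=best_k,
        weights=w / w.sum(), means=mu, variances=var,
        bic_by_k=bic_by_k, codes=codes, sample_ids=kept_ids,
    )


def discretize(expr: ExpressionMatrix, k_max: int, seed: int) -> RegimeMatrix:
    """Discretize every gene of an expression matrix into regimes.

    Deterministic for a given seed: each gene gets a sub-seed derived
    from (seed, gene index), so results do not depend on fit order.
    Per-gene failures (too few observed values) are flagged, not fatal.
    """
    samples = expr.sample_ids
    codes = pd.DataFrame(
        MISSING_CODE, index=expr.gene_ids, columns=samples, dtype=int
    )
    profiles: dict[str, RegimeProfile] = {}
    failed: list[str] = []
    for gi, gene in enumerate(expr.gene_ids):
        row = expr.values.loc[gene].to_numpy(dtype=float)
        try:
            prof = fit_gene_mixture(
                row, k_max=k_max, seed=_subseed(seed, gi),
                gene_id=gene, sample_ids=samples,
            )
        except DiscretizationError:
            failed.append(gene)
            continue
        profiles[gene] = prof
        codes.loc[gene, prof.sample_ids] = prof.codes
    return RegimeMatrix(codes=codes, profiles=profiles, k_max=k_max, failed_genes=failed)


def naive_std_bins(values: np.ndarray) -> np.ndarray:
    """Three-way binning after standardization to zero mean, unit variance.

    Bin 0: standardized value < -1.5; bin 1: the closed interval
    [-1.5, 1.5]; bin 2: > 1.5. A baseline discretization for comparison
    with the mixture-based regimes.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise DiscretizationError("naive_std_bins: zero standard deviation")
    z = (values - values.mean()) / sd
    return np.where(z < -1.5, 0, np.where(z > 1.5, 2, 1)).astype(int)


def occupancy_filter(rm: RegimeMatrix, min_fraction: float = 0.10) -> list[str]:
    """Genes whose every regime holds at least ceil(min_fraction * N) samples.

    N is the gene's non-missing sample count. Unimodal genes (k = 1) are
    dropped: they have no second regime to contrast.
    """
    if not (0 < min_fraction < 0.5):
        raise ValueError("min_fraction must be in (0, 0.5)")
    kept = []
    for gene, prof in rm.profiles.items():
        if prof.k < 2:
            continue
        n = len(prof.codes)
        need = math.ceil(min_fraction * n)
        if (prof.occupancy >= need).all():
            kept.append(gene)
    return kept


def write_regime_codes(rm: RegimeMatrix, path) -> None:
    rm.codes.to_csv(path, sep="\t", index_label="gene")


def read_regime_codes(path) -> RegimeMatrix:
    codes = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    codes.index = codes.index.astype(str)
    codes.index.name = None
    codes.columns = codes.columns.astype(str)
    return RegimeMatrix.from_codes(codes.astype(int))


def write_regime_profiles(rm: RegimeMatrix, path) -> None:
    """One row per (gene, component): weight, mean, variance, occupancy."""
    rows = []
    for gene, p in rm.profiles.items():
        occ = p.occupancy
        for c in range(p.k):
            rows.append(
                {"gene": gene, "k": p.k, "component": c,
                 "weight": p.weights[c], "mean": p.means[c],
                 "variance": p.variances[c], "occupancy": int(occ[c])}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
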