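"""Age-corrected Cox proportional-hazards screening of expression regimes.

For every bimodal gene, a Cox model with two covariates — patient age
(raw years) and a binary regime indicator (regime 1 coded as 1) — is
fit to the cohort's survival data. The reported hazard ratio is
max(exp(gamma), exp(-gamma)), the ratio for the regime with the poorer
prognosis, hence always >= 1. Genes whose regimes do not each cover at
least 10% of the samples are excluded so that ratios stay
representative. A sample-permutation null (regime codes shuffled
independently per gene) calibrates how large such ratios get by chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .discretize import MISSING_CODE, RegimeMatrix
from .io import ClinicalTable


class SurvivalError(ValueError):
    pass


@dataclass
class HazardResult:
    gene_id: str
    gamma: float  # Cox coefficient of the regime-1 indicator
    hr: float  # max(exp(gamma), exp(-gamma)), >= 1
    poor_regime: int  # regime with the poorer prognosis
    n_regime0: int
    n_regime1: int
    converged: bool


def cox_fit(
    time: np.ndarray, event: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Cox partial-likelihood fit; returns (coefficients, converged).

    Monotone likelihoods (perfect separation) are flagged as
    non-converged rather than raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == time.size and X.shape[1] != time.size:
        pass
    elif X.shape[1] == time.size:
        X = X.T
    if (time <= 0).any():
        raise SurvivalError("survival times must be > 0")
    if event.sum() < 1:
        raise SurvivalError("no events observed")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise SurvivalError(f"covariate {j} is constant")
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return np.full(X.shape[1], np.nan), False
    beta = cph.params_.to_numpy()
    converged = bool(np.isfinite(beta).all()) and float(np.abs(beta).max()) < 50
    return beta, converged


def gene_hazard_ratio(
    codes: np.ndarray,
    sample_ids: list[str],
    clinical: ClinicalTable,
    min_fraction: float = 0.10,
    gene_id: str = "",
) -> Optional[HazardResult]:
    """Age-adjusted hazard ratio for one gene's binary regimes.

    Returns None when the gene is excluded: occupancy of either regime
    below ceil(min_fraction * N) among clinically matched samples, or
    regimes other than {0, 1} present.
    """
    codes = np.asarray(codes)
    clin = clinical.table
    keep = [
        i for i, s in enumerate(sample_ids)
        if s in clin.index and codes[i] != MISSING_CODE
    ]
    if not keep:
        return None
    sub = codes[keep]
    if set(np.unique(sub)) - {0, 1}:
        raise SurvivalError(f"gene {gene_id!r}: expected binary regimes")
    samples = [sample_ids[i] for i in keep]
    n = len(samples)
    n1 = int((sub == 1).sum())
    n0 = n - n1
    need = math.ceil(min_fraction * n)
    if n0 < need or n1 < need:
        return None
    rows = clin.loc[samples]
    X = np.column_stack([rows["age"].to_numpy(), sub.astype(float)])
    try:
        beta, converged = cox_fit(
            rows["time"].to_numpy(), rows["event"].to_numpy(), X
        )
    except SurvivalError:
        return None
    gamma = float(beta[1]) if np.isfinite(beta[1]) else float("nan")
    if not converged or not np.isfinite(gamma):
        return HazardResult(gene_id, gamma, float("nan"), -1, n0, n1, False)
    hr = max(math.exp(gamma), math.exp(-gamma))
    poor = 1 if gamma > 0 else 0
    return HazardResult(gene_id, gamma, hr, poor, n0, n1, True)


def screen_hazards(
    rm: RegimeMatrix,
    clinical: ClinicalTable,
    min_fraction: float = 0.10,
) -> pd.DataFrame:
    """Hazard-ratio screen over all bimodal genes; one row per kept gene.

    Non-converged fits are flagged, never silently ranked; excluded
    genes (occupancy) do not appear.
    """
    samples = rm.sample_ids
    rows = []
    for gene in rm.gene_ids:
        prof = rm.profiles.get(gene)
        if prof is None or prof.k != 2:
            continue
        res = gene_hazard_ratio(
            rm.codes.loc[gene].to_numpy(), samples, clinical,
            min_fraction=min_fraction, gene_id=gene,
        )
        if res is None:
            continue
        rows.append(
            {"gene": res.gene_id, "gamma": res.gamma, "hr": res.hr,
             "poor_regime": res.poor_regime, "n_regime0": res.n_regime0,
             "n_regime1": res.n_regime1, "converged": res.converged}
        )
    df = pd.DataFrame(
        rows, columns=["gene", "gamma", "hr", "poor_regime",
                       "n_regime0", "n_regime1", "converged"],
    )
    if not df.empty:
        df = df.sort_values(
            "hr", ascending=False, kind="stable", na_position="last"
        ).reset_index(drop=True)
    return df


def permutation_null_hazards(
    rm: RegimeMatrix,
    clinical: ClinicalTable,
    n_perm: int,
    seed: int,
    min_fraction: float = 0.10,
) -> np.ndarray:
    """Null hazard-ratio distribution from per-gene sample permutations.

    For each permutation round, every gene's regime codes are shuffled
    across samples independently, severing any regime-survival link
    while preserving occupancies; the HRs of all rounds are pooled.
    """
    if n_perm < 0:
        raise SurvivalError("n_perm must be >= 0")
    rng = np.random.default_rng(seed)
    samples = rm.sample_ids
    hrs: list[float] = []
    genes = [g for g in rm.gene_ids if rm.profiles.get(g) and rm.k_of(g) == 2]
    for _ in range(n_perm):
        for gene in genes:
            codes = rm.codes.loc[gene].to_numpy().copy()
            rng.shuffle(codes)
            res = gene_hazard_ratio(
                codes, samples, clinical, min_fraction=min_fraction, gene_id=gene
            )
            if res is not None and res.converged:
                hrs.append(res.hr)
    return np.asarray(hrs)
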