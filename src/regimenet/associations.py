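"""Co-occurrence statistics between discrete events, MI, and ranked lists.

The central statistic is a one-sided binomial tail: for events A_i
(gene A in regime i; support n_a of n samples) and B_j (support n_b),
the null probability that both hold in one sample is p0 = n_a*n_b/n^2,
and the p-value is P(X >= n_ab) for X ~ Binomial(n, p0) — how much more
the two events co-occur than expected under independence. Only
enrichment is tested; depletion is out of scope.

The tail is evaluated in log space (exact log binomial coefficient plus
a ratio-recursion tail sum), because cohort-scale associations routinely
reach p ~ 1e-50 .. 1e-300 and beyond, far below what a linear-space
survival function can represent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import MISSING_CODE, RegimeMatrix
from .io import ExpressionMatrix

# below this linear-space p-value, switch to the exact log-space tail
_SF_UNDERFLOW_LOG10 = -280.0

_LN10 = math.log(10.0)


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class EventSet:
    """A (feature, category) event with its supporting sample set.

    The universal currency of the workflow: expression regimes,
    mutations, CNV states, and sample subgroups are all EventSets.
    """

    feature_id: str
    category: str  # regime index as str, or MUT / DEL / AMP / SUBGROUP
    support: frozenset
    universe_size: int
    universe: Optional[frozenset] = None  # sample ids the event is defined on

    def __post_init__(self) -> None:
        if len(self.support) > self.universe_size:
            raise AssociationError("event support exceeds universe")
        if self.universe is not None and not self.support <= self.universe:
            raise AssociationError("event support outside its universe")

    @property
    def n(self) -> int:
        return len(self.support)

    @property
    def label(self) -> str:
        return f"{self.feature_id}:{self.category}"


@dataclass
class AssociationRecord:
    """Counts, log10 p, conditionals and MI for one event pair."""

    event_a: EventSet
    event_b: EventSet
    n: int
    n_a: int
    n_b: int
    n_ab: int
    log10_p: float
    p_a_given_b: float
    p_b_given_a: float
    mi: float = float("nan")

    @property
    def expected(self) -> float:
        return self.n_a * self.n_b / self.n if self.n else 0.0


@dataclass
class RankedList:
    """Ranked unordered-pair keys with scores, best first."""

    measure: str
    pairs: list[tuple[str, str]]  # sorted gene-pair keys
    scores: list[float]

    def top(self, depth: int) -> set[tuple[str, str]]:
        if depth > len(self.pairs):
            raise AssociationError(
                f"depth {depth} exceeds list length {len(self.pairs)}"
            )
        return set(self.pairs[:depth])

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# elementary measures


def _log_binom_coeff(n: int, k: int) -> float:
    # exact for moderate n (log of an exact integer); lgamma for huge n
    if n <= 2000:
        return math.log(math.comb(n, k))
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def cooccurrence_log10_p(n_a: int, n_b: int, n_ab: int, n: int) -> float:
    """log10 of the one-sided binomial co-occurrence p-value.

    P(X >= n_ab) for X ~ Binomial(n, p0), p0 = n_a*n_b/n^2. Exact in log
    space for p-values down to ~1e-1000: the tail is accumulated from
    the log pmf at n_ab with the pmf ratio recursion
    pmf(k+1)/pmf(k) = (n-k)/(k+1) * p0/(1-p0).
    """
    if n <= 0:
        raise AssociationError("universe size n must be positive")
    if not (0 <= n_ab <= min(n_a, n_b) <= n):
        raise AssociationError(
            f"inconsistent counts: n_ab={n_ab}, n_a={n_a}, n_b={n_b}, n={n}"
        )
    if n_ab == 0:
        return 0.0
    p0 = (n_a / n) * (n_b / n)
    if p0 >= 1.0:
        return 0.0
    if p0 <= 0.0:
        # impossible under the null but observed: counts inconsistent
        raise AssociationError("n_ab > 0 with an empty marginal")
    mean = n * p0
    if n_ab <= mean:
        # moderate p (>= ~0.26): the linear-space survival function is exact enough
        return float(np.log10(stats.binom.sf(n_ab - 1, n, p0)))
    # log pmf at k = n_ab
    log_p0 = math.log(n_a) + math.log(n_b) - 2.0 * math.log(n)
    log_q0 = math.log1p(-p0)
    log_t0 = _log_binom_coeff(n, n_ab) + n_ab * log_p0 + (n - n_ab) * log_q0
    # tail sum relative to the first term; above the mean the ratio is < 1
    # and decreasing, so terms are monotone and the sum is modest
    ratio_const = p0 / (1.0 - p0)
    s = 1.0
    c = 0.0  # Kahan compensation
    term = 1.0
    for k in range(n_ab, n):
        term *= (n - k) / (k + 1) * ratio_const
        if term < 1e-20 * s:
            break
        y = term - c
        t = s + y
        c = (t - s) - y
        s = t
    return (log_t0 + math.log(s)) / _LN10


def _log10_tail_vec(
    n_a: np.ndarray, n_b: np.ndarray, n_ab: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized log10 tail: linear-space sf for the bulk, exact scalar
    log-space fallback wherever the sf underflows."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    n_ab_i = np.asarray(n_ab, dtype=int)
    p0 = n_a * n_b / (n * n)
    with np.errstate(divide="ignore"):
        sf = stats.binom.sf(n_ab_i - 1, n, np.clip(p0, 0.0, 1.0))
        out = np.log10(sf)
    out = np.where(n_ab_i == 0, 0.0, out)
    out = np.where(p0 >= 1.0, 0.0, out)
    bad = ~np.isfinite(out) | (out < _SF_UNDERFLOW_LOG10)
    for idx in np.argwhere(bad):
        i = tuple(idx)
        out[i] = cooccurrence_log10_p(
            int(n_a[i]), int(n_b[i]), int(n_ab_i[i]), n
        )
    return out


def conditional_probability(n_ab: int, n_b: int) -> float:
    """P(A_i | B_j) estimated as n_ab / n_b."""
    if n_b <= 0:
        raise AssociationError("conditioning event has empty support")
    if n_ab > n_b:
        raise AssociationError("n_ab exceeds n_b")
    return n_ab / n_b


def mutual_information(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete profiles.

    Computed over pairwise-complete samples (both codes observed);
    0 * log 0 terms vanish. Each term of the sum is itself a
    co-occurrence quantity: (n_ab/n) * ln(n_ab * n / (n_a * n_b)).
    """
    a = np.asarray(codes_a)
    b = np.asarray(codes_b)
    if a.shape != b.shape:
        raise AssociationError("code vectors differ in length")
    ok = (a != MISSING_CODE) & (b != MISSING_CODE)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        return 0.0
    joint = pd.crosstab(a, b).to_numpy().astype(float)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    return float(np.nansum(terms))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation on pairwise-complete continuous values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AssociationError("vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise AssociationError("need >= 3 pairwise-complete values")
    if x.std() == 0 or y.std() == 0:
        return float("nan")  # undefined-correlation flag
    return float(stats.pearsonr(x, y).statistic)


def bonferroni_threshold(
    alpha: float, n_feat: int, n_reg: int, m_feat: int, m_reg: int
) -> float:
    """Bonferroni-corrected p-value threshold for all cross-dataset tests.

    theta = alpha / (N * n_reg * M * m_reg), the conservative lower
    bound on significance used whenever a count of significant pairs is
    reported.
    """
    if min(alpha, n_feat, n_reg, m_feat, m_reg) <= 0:
        raise AssociationError("all threshold inputs must be positive")
    return alpha / (n_feat * n_reg * m_feat * m_reg)


# ---------------------------------------------------------------------------
# all-pairs scans


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def all_pairs_associations(
    rm: RegimeMatrix,
    measure: str = "cooccurrence",
    expr: Optional[ExpressionMatrix] = None,
) -> tuple[RankedList, pd.DataFrame]:
    """Score every gene pair and return a ranked list plus a record table.

    cooccurrence: every regime combination (i, j) of every multimodal
    gene pair is scored; the pair-level score is the minimum log10 p
    over combinations, reported with its achieving combination, ranked
    ascending. mi: plug-in MI on the code profiles, ranked descending.
    pearson: |r| on the continuous data (requires ``expr``), ranked
    descending. Unimodal genes are excluded from the discrete measures.
    Ties break on the lexicographic sorted gene-pair key.
    """
    if measure not in ("cooccurrence", "mi", "pearson"):
        raise AssociationError(f"unknown measure {measure!r}")
    if measure == "pearson":
        if expr is None:
            raise AssociationError("pearson requires the continuous expression matrix")
        return _all_pairs_pearson(expr)

    genes = rm.multimodal_genes()
    if len(genes) < 2:
        import warnings

        warnings.warn("fewer than 2 multimodal genes; empty association list")
        return RankedList(measure, [], []), _empty_table()

    codes = rm.codes.loc[genes].to_numpy()
    binary = all(rm.profiles[g].k == 2 for g in genes) and not (
        codes == MISSING_CODE
    ).any()
    if measure == "cooccurrence" and binary:
        table = _cooccurrence_binary_fast(genes, codes, rm.sample_ids)
    elif measure == "cooccurrence":
        table = _cooccurrence_generic(genes, rm)
    else:
        table = _mi_table(genes, codes)

    ranked = _rank_pairs(table, measure)
    return ranked, table


_TABLE_COLS = [
    "gene_a", "regime_a", "gene_b", "regime_b",
    "n", "n_a", "n_b", "n_ab", "expected",
    "log10_p", "p_a_given_b", "p_b_given_a", "mi",
]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_TABLE_COLS)


def _cooccurrence_binary_fast(
    genes: list[str], codes: np.ndarray, sample_ids: list[str]
) -> pd.DataFrame:
    """All regime-combination co-occurrence records for complete binary codes.

    Joint counts for the four combinations come from three matrix
    products; identical output to the generic per-pair path.
    """
    g = len(genes)
    n = codes.shape[1]
    high = (codes == 1).astype(np.float64)
    n1 = high.sum(axis=1)
    n11 = high @ high.T
    n10 = high @ (1.0 - high).T  # a high, b low
    # n01 = n10.T; n00 = n - n11 - n10 - n01
    iu, ju = np.triu_indices(g, k=1)
    mi_vals = _pairwise_mi_binary(high, n1, n11, iu, ju)
    rows = []
    for idx, (ia, ib) in enumerate(zip(iu, ju)):
        counts = {
            (1, 1): n11[ia, ib],
            (1, 0): n10[ia, ib],
            (0, 1): n10[ib, ia],
        }
        counts[(0, 0)] = n - counts[(1, 1)] - counts[(1, 0)] - counts[(0, 1)]
        na = {1: n1[ia], 0: n - n1[ia]}
        nb = {1: n1[ib], 0: n - n1[ib]}
        for (ra, rb), nab in counts.items():
            rows.append(
                (genes[ia], ra, genes[ib], rb, n,
                 int(na[ra]), int(nb[rb]), int(nab),
                 na[ra] * nb[rb] / n, 0.0,
                 nab / nb[rb] if nb[rb] else float("nan"),
                 nab / na[ra] if na[ra] else float("nan"),
                 mi_vals[idx])
            )
    table = pd.DataFrame(rows, columns=_TABLE_COLS)
    table["log10_p"] = _log10_tail_vec(
        table["n_a"].to_numpy(), table["n_b"].to_numpy(),
        table["n_ab"].to_numpy(), n,
    )
    return table


def _pairwise_mi_binary(
    high: np.ndarray, n1: np.ndarray, n11: np.ndarray,
    iu: np.ndarray, ju: np.ndarray,
) -> np.ndarray:
    n = high.shape[1]
    a1 = n1[iu]
    b1 = n1[ju]
    c11 = n11[iu, ju]
    c10 = a1 - c11
    c01 = b1 - c11
    c00 = n - c11 - c10 - c01
    total = np.zeros(len(iu))
    for cab, na, nb in (
        (c11, a1, b1), (c10, a1, n - b1), (c01, n - a1, b1), (c00, n - a1, n - b1)
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (cab / n) * np.log(cab * n / (na * nb))
        total += np.where(cab > 0, t, 0.0)
    return total


def _cooccurrence_generic(genes: list[str], rm: RegimeMatrix) -> pd.DataFrame:
    """Per-pair loop handling missing codes and k > 2; pairwise-complete N."""
    rows = []
    code_rows = {g: rm.codes.loc[g].to_numpy() for g in genes}
    for ia in range(len(genes)):
        for ib in range(ia + 1, len(genes)):
            ga, gb = genes[ia], genes[ib]
            a, b = code_rows[ga], code_rows[gb]
            ok = (a != MISSING_CODE) & (b != MISSING_CODE)
            av, bv = a[ok], b[ok]
            n = int(ok.sum())
            if n == 0:
                continue
            mi = mutual_information(av, bv)
            for ra in range(rm.profiles[ga].k):
                na = int((av == ra).sum())
                for rb in range(rm.profiles[gb].k):
                    nb = int((bv == rb).sum())
                    nab = int(((av == ra) & (bv == rb)).sum())
                    lp = cooccurrence_log10_p(na, nb, nab, n)
                    rows.append(
                        (ga, ra, gb, rb, n, na, nb, nab, na * nb / n, lp,
                         nab / nb if nb else float("nan"),
                         nab / na if na else float("nan"), mi)
                    )
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def _mi_table(genes: list[str], codes: np.ndarray) -> pd.DataFrame:
    rows = []
    for ia in range(len(genes)):
        for ib in range(ia + 1, len(genes)):
            mi = mutual_information(codes[ia], codes[ib])
            rows.append(
                (genes[ia], -1, genes[ib], -1, codes.shape[1],
                 0, 0, 0, 0.0, 0.0, float("nan"), float("nan"), mi)
            )
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def _all_pairs_pearson(expr: ExpressionMatrix) -> tuple[RankedList, pd.DataFrame]:
    vals = expr.values.to_numpy(dtype=float)
    genes = expr.gene_ids
    keep = [i for i in range(len(genes)) if np.nanstd(vals[i]) > 0]
    sub = vals[keep]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    rows = []
    for ii in range(len(keep)):
        for jj in range(ii + 1, len(keep)):
            ga, gb = genes[keep[ii]], genes[keep[jj]]
            rows.append((ga, -1, gb, -1, sub.shape[1], 0, 0, 0, 0.0, 0.0,
                         float("nan"), float("nan"), corr[ii, jj]))
    table = pd.DataFrame(rows, columns=_TABLE_COLS)
    table = table.rename(columns={"mi": "r"})
    scored = table.assign(
        key_a=np.minimum(table["gene_a"], table["gene_b"]),
        key_b=np.maximum(table["gene_a"], table["gene_b"]),
        score=-table["r"].abs(),
    ).sort_values(["score", "key_a", "key_b"], kind="stable")
    ranked = RankedList(
        "pearson",
        list(zip(scored["key_a"], scored["key_b"])),
        list(-scored["score"]),
    )
    return ranked, table


def _rank_pairs(table: pd.DataFrame, measure: str) -> RankedList:
    if table.empty:
        return RankedList(measure, [], [])
    t = table.assign(
        key_a=np.minimum(table["gene_a"], table["gene_b"]),
        key_b=np.maximum(table["gene_a"], table["gene_b"]),
    )
    if measure == "cooccurrence":
        best = (
            t.sort_values(["log10_p", "key_a", "key_b"], kind="stable")
            .groupby(["key_a", "key_b"], sort=False)
            .first()
            .reset_index()
        )
        best = best.sort_values(["log10_p", "key_a", "key_b"], kind="stable")
        scores = list(best["log10_p"])
    else:  # mi, descending
        best = t.drop_duplicates(["key_a", "key_b"])
        best = best.assign(neg=-best["mi"]).sort_values(
            ["neg", "key_a", "key_b"], kind="stable"
        )
        scores = list(best["mi"])
    return RankedList(measure, list(zip(best["key_a"], best["key_b"])), scores)


# ---------------------------------------------------------------------------
# cross-cohort comparison


def agreement_at_depth(
    list_a: RankedList, list_b: RankedList, depths: Sequence[int]
) -> list[float]:
    """Relative overlap |top-d(a) & top-d(b)| / d of two ranked lists.

    Walking down both cohorts' lists simultaneously: identical lists
    give 1 at every depth, disjoint lists 0.
    """
    out = []
    for d in depths:
        if d > min(len(list_a), len(list_b)):
            raise AssociationError(f"depth {d} exceeds a list length")
        out.append(len(list_a.top(d) & list_b.top(d)) / d)
    return out


def bimodal_intersection_filter(
    rm_a: RegimeMatrix, rm_b: RegimeMatrix
) -> list[str]:
    """Genes that are bimodal (k = 2) in both cohorts, matched by symbol."""
    shared = [
        g for g in rm_a.profiles
        if g in rm_b.profiles and rm_a.k_of(g) == 2 and rm_b.k_of(g) == 2
    ]
    if not shared:
        import warnings

        warnings.warn("no genes bimodal in both cohorts")
    return shared


def write_associations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
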