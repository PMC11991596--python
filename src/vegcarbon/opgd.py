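"""Optimal-parameter GeoDetector: factor, interaction and risk detection.

The q-statistic measures how much of a response's spatial variance a
stratification explains:

    q = 1 − Σ_h N_h σ_h² / (N σ²),   q ∈ [0, 1],

with population variances σ_h² within stratum h and σ² overall.  Continuous
factors are discretized by one of five classifiers (equal interval,
quantile, natural breaks, geometric interval, standard deviation) over a
range of stratum counts, and the (method, L) pair maximising q is kept —
the "optimal parameter" step.  Interaction detection compares the q of two
factors' cross-classification with each factor alone; risk detection
reports per-stratum mean response with Welch t-tests between strata and
the optimal (maximum-mean) stratum.

Significance of q uses the noncentral-F transformation from the
GeoDetector literature; a seeded permutation test is available as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DISCRETIZE_METHODS",
    "INTERACTION_TYPES",
    "FactorLayer",
    "QResult",
    "InteractionResult",
    "RiskResult",
    "discretize",
    "optimize_discretization",
    "factor_q",
    "permutation_p",
    "interaction_detect",
    "risk_detect",
]

DISCRETIZE_METHODS = ("equal", "quantile", "natural_breaks", "geometric", "std_dev")

INTERACTION_TYPES = (
    "nonlinear_enhancement",
    "linear_enhancement",      # "enhance, bi-": q12 exceeds both single factors
    "independence",
    "linear_weakening",        # "weaken, uni-": q12 between the single factors
    "nonlinear_weakening",
)

MIN_STRATUM_SIZE = 2
INDEPENDENCE_TOL = 1e-6


@dataclass
class FactorLayer:
    """Integer stratum codes 1..L over a 1-D sample vector."""

    strata: np.ndarray
    L: int
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        if self.strata.ndim != 1:
            raise ValueError("FactorLayer.strata must be 1-D (flatten rasters first)")
        codes = np.unique(self.strata)
        if codes.size and (codes.min() < 1 or codes.max() > self.L):
            raise ValueError(f"stratum codes must lie in 1..{self.L}")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.strata, minlength=self.L + 1)[1:]

    @classmethod
    def from_codes(cls, codes, name: str = "", provenance: dict | None = None) -> "FactorLayer":
        """Native categorical layer: arbitrary codes relabelled to 1..L."""
        codes = np.asarray(codes).ravel()
        uniq, relab = np.unique(codes, return_inverse=True)
        prov = {"kind": "native_categorical", "original_codes": uniq.tolist()}
        prov.update(provenance or {})
        return cls(relab.astype(np.int32) + 1, L=uniq.size, name=name, provenance=prov)


@dataclass
class QResult:
    q: float
    p: float
    n: int
    L: int
    stratum_sizes: np.ndarray
    stratum_variances: np.ndarray
    stratum_means: np.ndarray
    total_variance: float
    discretization: dict = field(default_factory=dict)


@dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    interaction_type: str


@dataclass
class RiskResult:
    stratum_means: np.ndarray
    stratum_sizes: np.ndarray
    optimal_stratum: int      # 1-based code of the maximum-mean stratum
    minimal_stratum: int
    pairwise_p: np.ndarray    # (L, L) Welch t-test p; NaN where untestable
    labels: list[str]


# ---------------------------------------------------------------------------
# Discretization


def _jenks_breaks(values: np.ndarray, L: int) -> np.ndarray:
    """Exact Fisher–Jenks natural breaks via dynamic programming (O(L n²));
    callers subsample large inputs."""
    x = np.sort(values.astype(float))
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(j, i):  # cost of one class covering x[j:i], j < i (vector in j)
        cnt = i - j
        tot = s1[i] - s1[j]
        return (s2[i] - s2[j]) - tot * tot / cnt

    cost = np.full((L + 1, n + 1), np.inf)
    cut = np.zeros((L + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, L + 1):
        for i in range(k, n + 1):
            j = np.arange(k - 1, i)
            cand = cost[k - 1, j] + sse(j, i)
            best = int(np.argmin(cand))
            cost[k, i] = cand[best]
            cut[k, i] = j[best]
    edges = []
    i = n
    for k in range(L, 0, -1):
        j = cut[k, i]
        if k > 1:
            edges.append((x[j - 1] + x[j]) / 2.0)
        i = j
    return np.array(sorted(edges))


def _breaks(values: np.ndarray, method: str, L: int, rng_cap: int = 2000) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if method == "equal":
        return np.linspace(lo, hi, L + 1)[1:-1]
    if method == "quantile":
        return np.quantile(values, np.arange(1, L) / L)
    if method == "natural_breaks":
        v = values
        if v.size > rng_cap:  # deterministic thinning for the O(n²) DP
            v = np.sort(v)[np.linspace(0, v.size - 1, rng_cap).astype(int)]
        return _jenks_breaks(v, L)
    if method == "geometric":
        shift = 0.0 if lo > 0 else 1e-9 - lo
        return np.exp(np.linspace(np.log(lo + shift), np.log(hi + shift), L + 1)[1:-1]) - shift
    if method == "std_dev":
        mu, sd = values.mean(), values.std()
        if sd == 0:
            raise ValueError("zero variance: std_dev breaks undefined")
        return mu + sd * (np.arange(1, L) - L / 2.0)
    raise ValueError(f"unknown discretization method {method!r}; "
                     f"choose from {DISCRETIZE_METHODS}")


def discretize(values, method: str, L: int, name: str = "") -> FactorLayer:
    """Classify a continuous sample vector into L ordered strata."""
    values = np.asarray(values, float).ravel()
    if not np.isfinite(values).all():
        raise ValueError("values must be finite (drop masked samples first)")
    if L < 2:
        raise ValueError("need at least 2 strata")
    n_distinct = np.unique(values).size
    if n_distinct < L:
        raise ValueError(
            f"factor {name or '<unnamed>'}: {n_distinct} distinct values cannot fill {L} strata")
    breaks = _breaks(values, method, L)
    codes = np.digitize(values, breaks).astype(np.int32) + 1
    # collapse empty strata so codes stay contiguous 1..L_eff
    uniq, relab = np.unique(codes, return_inverse=True)
    layer = FactorLayer(
        relab.astype(np.int32) + 1,
        L=uniq.size,
        name=name,
        provenance={"kind": "discretized", "method": method, "L_requested": L,
                    "breaks": np.asarray(breaks).tolist()},
    )
    return layer


# ---------------------------------------------------------------------------
# q statistic


def _q_decomposition(y: np.ndarray, codes: np.ndarray, L: int):
    n = y.size
    counts = np.bincount(codes, minlength=L + 1)[1:].astype(float)
    sums = np.bincount(codes, weights=y, minlength=L + 1)[1:]
    sq = np.bincount(codes, weights=y * y, minlength=L + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 0, sq / np.maximum(counts, 1) - means ** 2, np.nan)
    var = np.where(counts > 0, np.clip(var, 0.0, None), np.nan)
    total_var = float(y.var())
    ssw = float(np.nansum(counts * var))
    return counts, means, var, total_var, ssw


def factor_q(y, layer: FactorLayer, significance: str = "ncf",
             seed: int = 0, n_permutations: int = 999) -> QResult:
    """Eq-style q = 1 − Σ N_h σ_h² / (N σ²) with significance.

    ``significance='ncf'`` uses the noncentral-F transformation of q;
    ``'permutation'`` uses a seeded permutation test (q rank among
    stratum-label permutations); ``'none'`` skips the test (p = NaN).
    """
    y = np.asarray(y, float).ravel()
    if y.size != layer.strata.size:
        raise ValueError("response and strata differ in length")
    if not np.isfinite(y).all():
        raise ValueError("response must be finite (drop masked samples first)")
    N, L = y.size, layer.L
    if L < 2 or N < L:
        raise ValueError("need N >= L >= 2")
    counts, means, var, total_var, ssw = _q_decomposition(y, layer.strata, L)
    if total_var <= 0:
        raise ValueError("zero total variance: q undefined")
    q = 1.0 - ssw / (N * total_var)
    q = float(np.clip(q, 0.0, 1.0))
    if significance == "none":
        p = float("nan")
    elif significance == "permutation":
        p = permutation_p(y, layer, q, seed=seed, n_permutations=n_permutations)
    elif significance == "ncf":
        p = _ncf_p(y, counts, means, q, total_var)
    else:
        raise ValueError("significance must be 'ncf', 'permutation' or 'none'")
    return QResult(q=q, p=p, n=N, L=L, stratum_sizes=counts.astype(int),
                   stratum_variances=var, stratum_means=means,
                   total_variance=total_var,
                   discretization=dict(layer.provenance))


def _ncf_p(y: np.ndarray, counts: np.ndarray, means: np.ndarray,
           q: float, total_var: float) -> float:
    """Noncentral-F test for q (GeoDetector literature)."""
    N = y.size
    L = int((counts > 0).sum())
    if q >= 1.0:
        return 0.0
    f_val = (N - L) / max(L - 1, 1) * q / (1.0 - q)
    nz = counts > 0
    lam = (np.nansum(means[nz] ** 2 * 1.0)
           - (np.nansum(np.sqrt(counts[nz]) * means[nz])) ** 2 / N) / total_var
    lam = max(float(lam), 0.0)
    return float(stats.ncf.sf(f_val, L - 1, N - L, lam))


def permutation_p(y: np.ndarray, layer: FactorLayer, q_obs: float,
                  seed: int = 0, n_permutations: int = 999) -> float:
    """Seeded permutation p-value: share of label permutations with q ≥ q_obs."""
    rng = np.random.default_rng(seed)
    N, L = y.size, layer.L
    total_var = float(y.var())
    codes = layer.strata
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        _, _, _, _, ssw = _q_decomposition(perm, codes, L)
        if 1.0 - ssw / (N * total_var) >= q_obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Optimal-parameter search


def optimize_discretization(
    values,
    y,
    methods=DISCRETIZE_METHODS,
    L_range=range(3, 11),
    min_stratum_size: int = MIN_STRATUM_SIZE,
    name: str = "",
    significance: str = "ncf",
    seed: int = 0,
) -> tuple[FactorLayer, QResult]:
    """Search (method, L) combinations and return the q-maximising layer.

    Candidates with a stratum smaller than ``min_stratum_size`` are
    discarded.  Ties in q resolve to the smaller L, then to the earlier
    method in ``methods``.  The full search table travels in the returned
    ``QResult.discretization['search_table']``.
    """
    values = np.asarray(values, float).ravel()
    y = np.asarray(y, float).ravel()
    rows = []
    best = None  # (q, L, method_rank, layer, qresult)
    for rank, method in enumerate(methods):
        for L in L_range:
            try:
                layer = discretize(values, method, L, name=name)
            except ValueError:
                continue
            if layer.counts.min() < min_stratum_size:
                rows.append({"method": method, "L": L, "q": np.nan, "admissible": False})
                continue
            res = factor_q(y, layer, significance="none")
            rows.append({"method": method, "L": L, "q": res.q, "admissible": True})
            key = (-res.q, layer.L, rank)
            if best is None or key < best[0]:
                best = (key, layer, res)
    if best is None:
        raise ValueError(f"factor {name or '<unnamed>'}: no admissible (method, L) combination")
    _, layer, _ = best
    final = factor_q(y, layer, significance=significance, seed=seed)
    final.discretization["search_table"] = pd.DataFrame(rows)
    return layer, final


# ---------------------------------------------------------------------------
# Interaction detector


def _merge_small_strata(codes: np.ndarray, y: np.ndarray, min_size: int):
    """Merge strata below min_size into the stratum with the nearest mean y.

    Returns contiguous codes and the number of merges performed.
    """
    merges = 0
    while True:
        uniq, relab = np.unique(codes, return_inverse=True)
        codes = relab + 1
        L = uniq.size
        counts = np.bincount(codes, minlength=L + 1)[1:]
        if L <= 1 or counts.min() >= min_size:
            return codes.astype(np.int32), merges
        sums = np.bincount(codes, weights=y, minlength=L + 1)[1:]
        means = sums / counts
        small = int(np.argmin(counts)) + 1
        dist = np.abs(means - means[small - 1])
        dist[small - 1] = np.inf
        target = int(np.argmin(dist)) + 1
        codes = np.where(codes == small, target, codes)
        merges += 1


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = INDEPENDENCE_TOL) -> str:
    """Five-way interaction rule on (q1, q2, q12)."""
    s = q1 + q2
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - s) < tol:
        return "independence"
    if q12 > s:
        return "nonlinear_enhancement"
    if q12 > hi:
        return "linear_enhancement"
    if q12 >= lo:
        return "linear_weakening"
    return "nonlinear_weakening"


def interaction_detect(y, f1: FactorLayer, f2: FactorLayer,
                       min_stratum_size: int = MIN_STRATUM_SIZE) -> InteractionResult:
    """q of the two factors and of their cross-classification, typed.

    Cross strata smaller than ``min_stratum_size`` are merged into the
    nearest stratum by mean response before q12 is computed.
    """
    y = np.asarray(y, float).ravel()
    q1 = factor_q(y, f1, significance="none").q
    q2 = factor_q(y, f2, significance="none").q
    cross = (f1.strata.astype(np.int64) - 1) * f2.L + f2.strata
    codes, merges = _merge_small_strata(cross, y, min_stratum_size)
    layer12 = FactorLayer(codes, L=int(codes.max()), name=f"{f1.name}∩{f2.name}",
                          provenance={"kind": "cross", "merged_strata": merges})
    q12 = factor_q(y, layer12, significance="none").q
    return InteractionResult(q1=q1, q2=q2, q12=q12,
                             interaction_type=classify_interaction(q1, q2, q12))


# ---------------------------------------------------------------------------
# Risk detector


def risk_detect(y, layer: FactorLayer, labels: list[str] | None = None,
                alpha: float = 0.05) -> RiskResult:
    """Per-stratum mean response, optimal/minimal strata and Welch t-tests.

    Strata of size 1 keep their mean but are excluded from t-tests.
    """
    y = np.asarray(y, float).ravel()
    L = layer.L
    if L < 2:
        raise ValueError("risk detection needs at least 2 strata")
    counts, means, _, _, _ = _q_decomposition(y, layer.strata, L)
    groups = [y[layer.strata == h] for h in range(1, L + 1)]
    pmat = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            if counts[i] >= 2 and counts[j] >= 2:
                res = stats.ttest_ind(groups[i], groups[j], equal_var=False)
                pmat[i, j] = pmat[j, i] = float(res.pvalue)
    if labels is None:
        labels = [f"stratum_{h}" for h in range(1, L + 1)]
    if len(labels) != L:
        raise ValueError(f"{len(labels)} labels for {L} strata")
    valid = counts > 0
    opt = int(np.nanargmax(np.where(valid, means, -np.inf))) + 1
    mini = int(np.nanargmin(np.where(valid, means, np.inf))) + 1
    return RiskResult(stratum_means=means, stratum_sizes=counts.astype(int),
                      optimal_stratum=opt, minimal_stratum=mini,
                      pairwise_p=pmat, labels=list(labels))
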