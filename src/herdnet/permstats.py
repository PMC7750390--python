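"""Permutation inference for proximity networks.

All tests share one p-value rule: with observed statistic ``t_o`` and ``q``
permuted statistics ``t_p``,

    p = #(t_p >= t_o) / q,

and when no permuted statistic reaches the observed one the biased
estimator (q -> (0+1)/(q+1)) is substituted so p is never exactly zero.
Two-tailed comparisons feed the absolute centred statistic through the
same rule.  Node-level permutation means animal identities are shuffled
while the data structure is held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netmetrics import average_matrices
from .proximity import dyad_count

__all__ = [
    "PermutationResult",
    "DifferentiationResult",
    "MantelResult",
    "permutation_p",
    "bonferroni",
    "classify_lameness",
    "attribute_difference_matrix",
    "social_differentiation",
    "group_statistic_tests",
    "mantel_spearman",
    "temporal_block_comparison",
    "assortment_test",
    "correlate_daily_series",
]


# ---------------------------------------------------------------------------
# core permutation arithmetic


def permutation_p(t_o: float, t_p: np.ndarray, biased_if_zero: bool = True) -> float:
    """Upper-tail permutation p-value with optional biased-zero correction."""
    t_p = np.asarray(t_p, dtype=float)
    if t_p.size == 0:
        raise ValueError("permuted sample must be nonempty")
    if not np.isfinite(t_o) or not np.all(np.isfinite(t_p)):
        raise ValueError("statistics must be finite")
    q = t_p.size
    count = int((t_p >= t_o).sum())
    if count == 0 and biased_if_zero:
        return 1.0 / (q + 1)
    return count / q


def bonferroni(p_values, m: int):
    """p_adj = min(1, p * m); m must cover the whole comparison battery."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m < arr.size:
        raise ValueError("m must be >= number of p-values")
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = np.minimum(1.0, arr * m)
    return float(adj[0]) if np.isscalar(p_values) or np.ndim(p_values) == 0 else adj


@dataclass
class PermutationResult:
    test: str
    t_o: float
    t_p: np.ndarray = field(repr=False)
    q: int = 0
    p: float = 1.0
    p_adjusted: float | None = None
    seed: int | None = None


@dataclass
class MantelResult:
    r_s: float
    p: float
    q: int
    p_adjusted: float | None = None
    seed: int | None = None


@dataclass
class DifferentiationResult:
    S: float
    expected: float
    observed: np.ndarray = field(repr=False)
    squared_deviation: np.ndarray = field(repr=False)
    differentiated: np.ndarray = field(repr=False)  # per-dyad flags
    differentiated_fraction: float = 0.0
    p: float = 1.0
    q: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# attributes


def classify_lameness(scores) -> str:
    """Two-group lameness class from three fortnightly mobility scores.

    Per session a score of 2-3 is lame (L), 0-1 non-lame (NL).  All-NL and
    dominant-NL sequences (NL-NL-L, L-NL-NL) are 'non_lame'; all-L and
    dominant-L sequences (L-L-NL, NL-L-L) are 'lame'; sequences changing
    status twice (NL-L-NL, L-NL-L) or containing a missing score (NS) are
    'excluded'.
    """
    if len(scores) != 3:
        raise ValueError("expected exactly 3 scoring sessions")
    states = []
    for s in scores:
        if isinstance(s, str):
            if s.upper() == "NS":
                return "excluded"
            raise ValueError(f"invalid mobility score {s!r}")
        if s not in (0, 1, 2, 3):
            raise ValueError(f"invalid mobility score {s!r}")
        states.append("L" if s >= 2 else "NL")
    pattern = "-".join(states)
    if pattern in ("NL-NL-NL", "NL-NL-L", "L-NL-NL"):
        return "non_lame"
    if pattern in ("L-L-L", "L-L-NL", "NL-L-L"):
        return "lame"
    return "excluded"  # NL-L-NL or L-NL-L


def attribute_difference_matrix(
    attributes: pd.DataFrame, attr_field: str
) -> pd.DataFrame:
    """Symmetric |value_a - value_b| matrix over the included animals.

    ``attr_field`` is 'parity', 'days_in_milk' or 'lameness'; lameness is
    coded 1/0 over the classified (non-excluded) subset.  Animals with a
    missing value are excluded with a warning, never imputed.
    """
    df = attributes.set_index("animal_id")
    if attr_field == "lameness":
        cls = df["lameness_class"]
        keep = cls.isin(["lame", "non_lame"])
        vals = cls[keep].map({"lame": 1.0, "non_lame": 0.0})
    else:
        if attr_field not in df.columns:
            raise ValueError(f"unknown attribute field {attr_field!r}")
        vals = df[attr_field].astype(float)
        missing = vals.isna()
        if missing.any():
            warnings.warn(
                f"excluding {int(missing.sum())} animals with missing {attr_field}",
                stacklevel=2,
            )
            vals = vals[~missing]
    if len(vals) < 2:
        raise ValueError("fewer than 2 animals with usable attribute values")
    a = vals.to_numpy()
    d = np.abs(a[:, None] - a[None, :])
    out = pd.DataFrame(d, index=vals.index, columns=vals.index)
    np.fill_diagonal(out.values, np.nan)
    return out


# ---------------------------------------------------------------------------
# social differentiation


def _upper(matrix: pd.DataFrame) -> np.ndarray:
    v = matrix.to_numpy(dtype=float)
    iu = np.triu_indices(v.shape[0], 1)
    return v[iu]


def social_differentiation(
    matrix: pd.DataFrame, q: int = 10_000, seed: int | None = None
) -> DifferentiationResult:
    """Mean squared deviation of dyadic counts from the uniform null.

    With observed counts O_ij and E_ij = (grand total)/(number of dyads),
    S = sum over dyads (O_ij - E_ij)^2 / dyad_count -- algebraically equal
    to the ordered double sum divided by n(n-1).  The null redistributes
    the day's total uniformly at random over dyads (multinomial); per-dyad
    differentiation is flagged where the squared deviation exceeds the
    null's 95th percentile.
    """
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 animals")
    obs = _upper(matrix)
    D = dyad_count(n)
    total = float(np.nansum(obs))
    E = total / D
    sqdev = (obs - E) ** 2
    S = float(sqdev.mean())
    if total <= 0:
        warnings.warn("zero total interactions: S = 0, p = 1", stacklevel=2)
        flags = np.zeros_like(obs, dtype=bool)
        return DifferentiationResult(0.0, 0.0, obs, sqdev, flags, 0.0, 1.0, q, seed)
    rng = np.random.default_rng(seed)
    total_i = int(round(total))
    s_perm = np.empty(q)
    thresh_samples = []
    chunk = max(1, min(q, int(2e7 // max(D, 1))))
    done = 0
    while done < q:
        k = min(chunk, q - done)
        draws = rng.multinomial(total_i, np.full(D, 1.0 / D), size=k).astype(float)
        dev2 = (draws - E) ** 2
        s_perm[done : done + k] = dev2.mean(axis=1)
        # subsample for the per-dyad exceedance threshold to bound memory
        thresh_samples.append(dev2[: min(k, 200)].ravel())
        done += k
    p = permutation_p(S, s_perm)
    thr = float(np.quantile(np.concatenate(thresh_samples), 0.95))
    flags = sqdev > thr
    return DifferentiationResult(
        S, E, obs, sqdev, flags, float(flags.mean()), p, q, seed
    )


# ---------------------------------------------------------------------------
# rank-based group comparisons


def _kw_statistic_from_ranksums(
    rank_sums: np.ndarray, group_sizes: np.ndarray, N: int, tie_correction: float
) -> np.ndarray:
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums**2 / group_sizes, axis=-1) - 3.0 * (
        N + 1
    )
    return h / tie_correction


def _tie_correction(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    N = values.size
    c = 1.0 - float(((counts**3 - counts).sum())) / (N**3 - N)
    return c if c > 0 else 1.0


def group_statistic_tests(
    data,
    design: str,
    q: int = 10_000,
    seed: int | None = None,
    labels=None,
) -> PermutationResult:
    """Permuted rank tests over per-cow daily summaries.

    designs:
      * ``interindividual_kw`` -- data is a (cows x days) frame/array of
        daily interaction totals; groups are cows; the null shuffles cow
        identities within each day.
      * ``betweenday_kw`` -- same data; groups are days; the null shuffles
        day labels within each cow.
      * ``wilcoxon`` -- data is a vector of per-cow summaries and
        ``labels`` a matching binary group vector; two-tailed via the
        absolute centred Mann-Whitney statistic; the null shuffles group
        labels across cows.
    """
    rng = np.random.default_rng(seed)
    if design in ("interindividual_kw", "betweenday_kw"):
        X = np.asarray(
            data.to_numpy() if isinstance(data, pd.DataFrame) else data, dtype=float
        )
        if X.ndim != 2 or min(X.shape) < 2:
            raise ValueError("need a (cows x days) array with both dims >= 2")
        n_cows, n_days = X.shape
        N = X.size
        ranks = stats.rankdata(X.ravel()).reshape(X.shape)
        tie_c = _tie_correction(X.ravel())
        if design == "interindividual_kw":
            sizes = np.full(n_cows, n_days, dtype=float)
            t_o = float(
                _kw_statistic_from_ranksums(ranks.sum(axis=1), sizes, N, tie_c)
            )
            t_p = np.empty(q)
            for b in range(q):
                shuffled = np.empty_like(ranks)
                for dcol in range(n_days):
                    shuffled[:, dcol] = ranks[rng.permutation(n_cows), dcol]
                t_p[b] = _kw_statistic_from_ranksums(
                    shuffled.sum(axis=1), sizes, N, tie_c
                )
        else:
            sizes = np.full(n_days, n_cows, dtype=float)
            t_o = float(
                _kw_statistic_from_ranksums(ranks.sum(axis=0), sizes, N, tie_c)
            )
            t_p = np.empty(q)
            for b in range(q):
                shuffled = np.empty_like(ranks)
                for crow in range(n_cows):
                    shuffled[crow] = ranks[crow, rng.permutation(n_days)]
                t_p[b] = _kw_statistic_from_ranksums(
                    shuffled.sum(axis=0), sizes, N, tie_c
                )
        p = permutation_p(t_o, t_p)
        return PermutationResult(design, t_o, t_p, q, p, seed=seed)

    if design == "wilcoxon":
        x = np.asarray(data, dtype=float)
        lab = np.asarray(labels)
        if x.ndim != 1 or lab.shape != x.shape:
            raise ValueError("wilcoxon design needs a value vector and matching labels")
        groups = np.unique(lab)
        if groups.size != 2:
            raise ValueError("wilcoxon design needs exactly 2 groups")
        n_a = int((lab == groups[0]).sum())
        n_b = x.size - n_a
        if min(n_a, n_b) < 2:
            raise ValueError("group sizes must be >= 2")
        ranks = stats.rankdata(x)
        mu = n_a * (x.size + 1) / 2.0  # null mean of group-A rank sum
        t_o = abs(float(ranks[lab == groups[0]].sum()) - mu)
        t_p = np.empty(q)
        mask = lab == groups[0]
        for b in range(q):
            t_p[b] = abs(float(ranks[rng.permutation(x.size)][:n_a].sum()) - mu)
        p = permutation_p(t_o, t_p)
        return PermutationResult("wilcoxon", t_o, t_p, q, p, seed=seed)

    raise ValueError(f"unknown design {design!r}")


def wilcoxon_w(x: np.ndarray, labels: np.ndarray, group) -> float:
    """R-convention Wilcoxon W (Mann-Whitney U of ``group``), for reporting."""
    x = np.asarray(x, dtype=float)
    lab = np.asarray(labels)
    ranks = stats.rankdata(x)
    n_g = int((lab == group).sum())
    return float(ranks[lab == group].sum() - n_g * (n_g + 1) / 2.0)


# ---------------------------------------------------------------------------
# Mantel matrix correlation


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def mantel_spearman(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    q: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Spearman Mantel correlation with node-label permutation null.

    R_s is the Spearman rank correlation of the two matrices' upper
    triangles; the null permutes one matrix's rows and columns
    simultaneously ``q`` times; p is one-sided (>=) through the common
    permutation rule.
    """
    if isinstance(m1, pd.DataFrame) and isinstance(m2, pd.DataFrame):
        if not (m1.index.equals(m2.index) and m1.columns.equals(m2.columns)):
            raise ValueError("matrices must share roster and ordering")
    a1 = np.asarray(m1, dtype=float)
    a2 = np.asarray(m2, dtype=float)
    if a1.shape != a2.shape or a1.shape[0] != a1.shape[1]:
        raise ValueError("matrices must be square with equal dimension")
    n = a1.shape[0]
    iu = np.triu_indices(n, 1)
    v1 = a1[iu]
    v2 = a2[iu]
    for v, name in ((v1, "m1"), (v2, "m2")):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant: ranks undefined")
    r1 = stats.rankdata(v1)
    r1c = r1 - r1.mean()
    denom1 = np.sqrt((r1c**2).sum())

    def _rs(vals2: np.ndarray) -> np.ndarray:
        r2 = _rank_rows(vals2)
        r2c = r2 - r2.mean(axis=-1, keepdims=True)
        denom2 = np.sqrt((r2c**2).sum(axis=-1))
        return (r2c @ r1c) / (denom1 * denom2)

    r_obs = float(_rs(v2[None, :])[0])
    rng = np.random.default_rng(seed)
    t_p = np.empty(q)
    chunk = max(1, min(q, int(4e7 // max(v1.size, 1))))
    done = 0
    while done < q:
        k = min(chunk, q - done)
        block = np.empty((k, v1.size))
        for b in range(k):
            perm = rng.permutation(n)
            block[b] = a2[np.ix_(perm, perm)][iu]
        t_p[done : done + k] = _rs(block)
        done += k
    p = permutation_p(r_obs, t_p)
    return MantelResult(r_obs, p, q, seed=seed)


def temporal_block_comparison(
    daily_matrices: list[pd.DataFrame],
    block_days: int = 4,
    q: int = 10_000,
    seed: int | None = None,
) -> list[MantelResult]:
    """Mantel comparisons of consecutive block-averaged networks.

    Days are tiled into blocks of ``block_days`` (trailing partial block
    dropped), block matrices are element-wise means, and each consecutive
    pair is compared; Bonferroni is applied over the (#blocks - 1)
    comparisons.
    """
    if block_days < 1:
        raise ValueError("block_days must be >= 1")
    n_blocks = len(daily_matrices) // block_days
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks")
    blocks = [
        average_matrices(daily_matrices[i * block_days : (i + 1) * block_days])
        for i in range(n_blocks)
    ]
    m = n_blocks - 1
    rng = np.random.default_rng(seed)
    results = []
    for i in range(m):
        sub = int(rng.integers(2**31))
        res = mantel_spearman(blocks[i], blocks[i + 1], q=q, seed=sub)
        res.p_adjusted = bonferroni(res.p, m)
        results.append(res)
    return results


def assortment_test(
    interaction_matrix: pd.DataFrame,
    attr_diff_matrix: pd.DataFrame,
    q: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test of an interaction matrix against an attribute-difference matrix.

    Negative R_s means similar animals interact more.  Rosters must match;
    a degenerate (all-equal) attribute matrix is an error.  Bonferroni
    over days is applied by the calling battery.
    """
    common = [a for a in interaction_matrix.index if a in set(attr_diff_matrix.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 animals shared between matrices")
    im = interaction_matrix.loc[common, common]
    am = attr_diff_matrix.loc[common, common]
    return mantel_spearman(im, am, q=q, seed=seed)


def correlate_daily_series(series_a, series_b) -> tuple[float, float]:
    """Pearson correlation of two daily series with two-sided p."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("series must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance series")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
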