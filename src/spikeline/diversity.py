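"""Normalisation, alpha/beta diversity, ordination and PERMANOVA.

Implements the statistics from first principles on top of numpy/scipy:
centred log-ratio (CLR) normalisation with a pseudo-count offset,
rarefaction without replacement, Hill-number alpha diversity (richness,
exp-Shannon, inverse Simpson), rarefaction curves with bootstrap
confidence bands, Euclidean and Bray–Curtis distances, principal
coordinates analysis via Gower centering, sequential-term PERMANOVA with
a permutation pseudo-F test, and exact/approximate Wilcoxon rank-sum
comparisons of alpha indices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .model import CountTable, DistanceMatrix, PermanovaResult, ValidationError

__all__ = [
    "clr_normalize",
    "default_rarefaction_depth",
    "rarefy",
    "alpha_diversity",
    "hill_number",
    "re_curves",
    "distance",
    "pcoa",
    "permanova",
    "compare_alpha",
]


def clr_normalize(table: CountTable | pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform with a pseudo-count offset.

    Each sample row x becomes ``ln(x + offset) − mean(ln(x + offset))``, so
    row means are exactly zero. The default offset of 1 keeps zero counts
    finite.
    """
    df = table.data if isinstance(table, CountTable) else table
    arr = df.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    if offset <= 0 and np.any(arr == 0):
        raise ValidationError("offset must be > 0 when zero counts are present")
    logged = np.log(arr + offset)
    centred = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred, index=df.index, columns=df.columns)


def default_rarefaction_depth(table: CountTable, fraction: float = 0.99) -> int:
    """Default depth: floor(fraction × minimum sample total)."""
    return int(math.floor(fraction * table.totals.min()))


def rarefy(
    table: CountTable,
    depth: int | None = None,
    seed: int | None = 0,
) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    ``depth`` defaults to 99% of the minimum sample total. Samples whose
    total is below ``depth`` are dropped with a warning. Reproducible from
    ``seed`` (one multivariate hypergeometric draw per sample).
    """
    if depth is None:
        depth = default_rarefaction_depth(table)
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.totals
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        warnings.warn(f"samples below depth {depth} dropped: {dropped}", stacklevel=2)
    if not keep:
        raise ValidationError("no sample reaches the rarefaction depth")
    rows = []
    for s in keep:
        counts = table.data.loc[s].to_numpy()
        if totals[s] == depth:
            rows.append(counts.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    return CountTable(pd.DataFrame(rows, index=keep, columns=table.sv_ids))


def _alpha_row(counts: np.ndarray) -> tuple[float, float, float]:
    total = counts.sum()
    if total == 0:
        return (np.nan, np.nan, np.nan)
    p = counts[counts > 0] / total
    s = float(len(p))
    h = float(-(p * np.log(p)).sum())
    d2 = float(1.0 / np.square(p).sum())
    return (s, h, d2)


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness S, Shannon H (natural log) and inverse Simpson D2.

    Empty samples yield a null (NaN) row. ``S >= 1`` for non-empty samples,
    ``H <= ln S`` and ``D2 <= S`` always hold.
    """
    rows = [_alpha_row(table.data.loc[s].to_numpy()) for s in table.sample_ids]
    return pd.DataFrame(rows, index=table.sample_ids, columns=["S", "H", "D2"])


def hill_number(counts: np.ndarray, q: int) -> float:
    """Hill number of order q ∈ {0, 1, 2} for one count vector."""
    s, h, d2 = _alpha_row(np.asarray(counts))
    if q == 0:
        return s
    if q == 1:
        return float(np.exp(h))
    if q == 2:
        return d2
    raise ValidationError("q must be 0, 1 or 2")


def re_curves(
    table: CountTable,
    q_set: Iterable[int] = (0, 1, 2),
    grid: Sequence[int] | None = None,
    n_boot: int = 200,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sample-size-based rarefaction curves for Hill numbers with bootstrap CI.

    For each sample and grid size m <= observed total, the Hill number of
    order q is computed on hypergeometric (without-replacement) subsamples;
    the point estimate is the mean over ``n_boot`` resamples and the CI the
    2.5/97.5 percentiles. Within one resample the subsamples are nested
    (prefixes of one shuffled read sequence), so the q = 0 curve is
    non-decreasing in m for every resample and hence in the mean. Grid
    points beyond a sample's total are skipped with a warning
    (interpolation only). At m = total the estimate equals the observed
    Hill number exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in table.sample_ids:
        counts = table.data.loc[s].to_numpy()
        total = int(counts.sum())
        if total == 0:
            continue
        sample_grid = list(grid) if grid is not None else sorted(
            set(np.linspace(1, total, 10, dtype=int))
        )
        usable = [m for m in sample_grid if 1 <= m <= total]
        skipped = [m for m in sample_grid if m > total]
        if skipped:
            warnings.warn(f"{s}: grid points above total skipped: {skipped}", stacklevel=2)
        labels = np.repeat(np.arange(len(counts)), counts)
        n_sv = len(counts)
        q_list = list(q_set)
        vals = {(q, m): np.empty(n_boot) for q in q_list for m in usable}
        for b in range(n_boot):
            perm = rng.permutation(labels)
            for m in usable:
                sub = np.bincount(perm[:m], minlength=n_sv)
                for q in q_list:
                    vals[(q, m)][b] = hill_number(sub, q)
        for q in q_list:
            for m in usable:
                v = vals[(q, m)]
                rows.append(
                    {
                        "sample_id": s,
                        "q": q,
                        "m": m,
                        "estimate": float(v.mean()),
                        "ci_low": float(np.percentile(v, 2.5)),
                        "ci_high": float(np.percentile(v, 97.5)),
                    }
                )
    return pd.DataFrame(rows)


def distance(
    data: CountTable | pd.DataFrame,
    metric: str = "euclidean",
) -> DistanceMatrix:
    """Pairwise sample distances: Euclidean (for CLR input) or Bray–Curtis.

    Euclidean expects CLR-transformed values, Bray–Curtis count data; a
    mismatch (negative values under Bray–Curtis) raises, while Euclidean on
    raw counts merely warns.
    """
    df = data.data if isinstance(data, CountTable) else data
    arr = df.to_numpy(dtype=float)
    if metric == "euclidean":
        if np.all(arr >= 0) and not isinstance(data, pd.DataFrame):
            warnings.warn(
                "euclidean distance on raw counts; CLR-transformed input expected",
                stacklevel=2,
            )
        d = squareform(pdist(arr, metric="euclidean"))
    elif metric in ("bray-curtis", "braycurtis"):
        if np.any(arr < 0):
            raise ValidationError("Bray–Curtis requires non-negative input")
        d = squareform(pdist(arr, metric="braycurtis"))
        d = np.nan_to_num(d, nan=0.0)  # two all-zero samples are identical
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=list(df.index), data=d, metric=metric)


def pcoa(dist: DistanceMatrix) -> dict:
    """Principal coordinates analysis by Gower centering.

    Eigendecomposes ``B = −½ J D² J`` (J the centering matrix). Returns
    coordinates for positive eigenvalues (scaled by sqrt(eigenvalue)) and
    the full eigenvalue spectrum, negative eigenvalues included and
    uncorrected. The eigenvalue sum equals trace(B).
    """
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if np.allclose(d, 0):
        warnings.warn("all-zero distance matrix; coordinates are zero", stacklevel=2)
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return {
        "coordinates": pd.DataFrame(coords, index=dist.sample_ids, columns=cols),
        "eigenvalues": eigvals,
        "proportion_explained": np.where(eigvals > 0, eigvals, 0) / eigvals[pos].sum()
        if pos.any()
        else np.zeros(n),
    }


def _gower_matrix(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    return (g + g.T) / 2.0


def _design_columns(values: pd.Series) -> np.ndarray:
    """Model-matrix columns for one term (dummy coding, first level dropped)."""
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 2:
        return values.to_numpy(dtype=float).reshape(-1, 1)
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValidationError(f"term {values.name!r} is constant")
    cols = [(values == lv).to_numpy(dtype=float) for lv in levels[1:]]
    return np.column_stack(cols)


def permanova(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Partitions the total sum of squares of the Gower-centred matrix G over
    the ordered ``terms`` using hat matrices of the cumulative design
    (McArdle–Anderson): ``SS_k = tr(H_k G) − tr(H_{k−1} G)``. The pseudo-F
    for each term uses the residual of the full model. p-values come from
    simultaneous permutation of sample labels (rows/columns of G):
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``. With ``exhaustive=True`` all
    n! label permutations are enumerated instead and
    ``p = #{F* >= F} / n!`` (the identity counts itself).
    """
    ids = dist.sample_ids
    n = len(ids)
    meta = metadata.loc[ids]
    g = _gower_matrix(dist.data)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    h_prev = x @ np.linalg.pinv(x)
    dfs = []
    hats = []
    for term in terms:
        if term not in meta.columns:
            raise ValidationError(f"term {term!r} not in metadata")
        cols = _design_columns(meta[term])
        x = np.column_stack([x, cols])
        h = x @ np.linalg.pinv(x)
        rank_gain = int(round(np.trace(h) - np.trace(h_prev)))
        if rank_gain == 0:
            raise ValidationError(f"term {term!r} is confounded with earlier terms")
        dfs.append(rank_gain)
        hats.append((h_prev, h))
        h_prev = h
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum((h - h0) * gmat.T)) for h0, h in hats])
        ss_res = float(np.trace(gmat)) - ss.sum()
        return ss, ss_res

    ss_terms, ss_res = term_stats(g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    if exhaustive:
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
            count += f_p >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
            count += f_p >= f_obs
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[i],
                "sum_sq": ss_terms[i],
                "F": f_obs[i],
                "R2": ss_terms[i] / ss_total,
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss_res,
            "F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
        }
    )
    return PermanovaResult(
        table=pd.DataFrame(rows).set_index("term"),
        n_permutations=n_used,
        seed=seed,
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by exhaustive enumeration (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    e_w = ranks.sum() * n1 / len(pooled)
    w_obs = ranks[:n1].sum()
    dev_obs = abs(w_obs - e_w)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        if abs(w - e_w) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def compare_alpha(
    alpha_table: pd.DataFrame,
    grouping: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Two-sample Wilcoxon rank-sum p-values per alpha index.

    Exactly two groups with >= 2 samples each are required. For groups of
    up to 10 samples each the p-value is exact (exhaustive enumeration of
    rank assignments, midranks for ties); larger groups use the normal
    approximation with tie correction. Rank-based, hence invariant to
    monotone transforms of the index values.
    """
    grouping = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    groups = pd.unique(grouping)
    if len(groups) != 2:
        raise ValidationError("exactly two groups required; compare pairs for more")
    ids1 = [s for s in alpha_table.index if grouping.get(s) == groups[0]]
    ids2 = [s for s in alpha_table.index if grouping.get(s) == groups[1]]
    if len(ids1) < 2 or len(ids2) < 2:
        raise ValidationError("each group needs >= 2 samples")
    out = {}
    for col in alpha_table.columns:
        x = alpha_table.loc[ids1, col].to_numpy(dtype=float)
        y = alpha_table.loc[ids2, col].to_numpy(dtype=float)
        if max(len(x), len(y)) <= 10:
            out[col] = _exact_rank_sum_p(x, y)
        else:
            pooled = np.concatenate([x, y])
            ranks = pd.Series(pooled).rank().to_numpy()
            n1, n2 = len(x), len(y)
            n = n1 + n2
            w = ranks[:n1].sum()
            e_w = n1 * (n + 1) / 2.0
            _, tie_counts = np.unique(pooled, return_counts=True)
            tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
            var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
            if var_w <= 0:
                out[col] = 1.0
                continue
            z = (w - e_w) / math.sqrt(var_w)
            out[col] = float(2.0 * norm.sf(abs(z)))
    return pd.Series(out)
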