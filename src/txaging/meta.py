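"""Cross-dataset and cross-species comparison of aging profiles.

Profiles are rows of interval fold changes over a shared gene universe,
standardized by dividing each row by its own standard deviation so that
profiles from different tissues and platforms are comparable; profiles are
clustered on correlation distance. Cross-species agreement over 1:1
ortholog pairs is assessed three ways: a 3x3 direction contingency with
adjusted residuals, a rank-based Wilcoxon-Mann-Whitney z statistic, and a
running-sum enrichment score calibrated by random-foreground permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ProfileMatrix",
    "standardize_profiles",
    "cluster_profiles",
    "rank_genes_by_support",
    "overlap_percentage",
    "ContingencySummary",
    "contingency_adjusted_residuals",
    "RankEnrichmentResult",
    "auc_rank_enrichment",
    "PermutationESResult",
    "permutation_enrichment_score",
    "correlate_orthologs",
    "read_ortholog_map",
]

_DIRECTIONS = ("up", "ns", "down")


@dataclass
class ProfileMatrix:
    fc: pd.DataFrame  # profiles x genes, interval fold changes
    standardized: pd.DataFrame  # fc / per-row sd (constant rows NaN)
    row_sd: pd.Series
    constant_rows: list[str]
    species: pd.Series | None = None


def standardize_profiles(fc: pd.DataFrame, species: pd.Series | None = None) -> ProfileMatrix:
    """Divide each profile row by the standard deviation of its fold changes.

    Standardized rows have unit standard deviation; constant rows are
    flagged and left NaN (they carry no ordering information and are
    excluded from clustering).
    """
    if fc.shape[1] < 2:
        raise ValueError("profiles need at least 2 genes")
    sd = fc.std(axis=1, ddof=1)
    constant = sd.index[sd == 0].tolist()
    standardized = fc.div(sd.replace(0, np.nan), axis=0)
    return ProfileMatrix(fc=fc, standardized=standardized, row_sd=sd, constant_rows=constant, species=species)


def cluster_profiles(matrix: ProfileMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering on 1 - Pearson correlation of profiles.

    Constant (zero-variance) rows are excluded with a warning via the
    returned label list; profile order (hence tie-breaking) follows the
    label sort order for determinism. Returns (linkage matrix, labels).
    """
    usable = [p for p in matrix.standardized.index if p not in matrix.constant_rows]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-constant profiles")
    labels = sorted(usable)
    X = matrix.standardized.loc[labels].to_numpy()
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, labels


def rank_genes_by_support(
    directions: pd.DataFrame,
    standardized_fc: pd.DataFrame | None = None,
    top: int = 50,
) -> dict[str, pd.DataFrame]:
    """Genes ranked by how many profiles call them the same direction.

    ``directions`` is profiles x genes with values in {up, ns, down}. For
    each direction, genes are ranked by the count of supporting profiles
    (descending), ties broken by the mean standardized fold-change magnitude
    when available, then by gene id. Genes with zero support are dropped.
    """
    if directions.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    out = {}
    for direction in ("up", "down"):
        support = (directions == direction).sum(axis=0)
        support = support[support > 0]
        if standardized_fc is not None:
            tie = standardized_fc.mean(axis=0).abs().reindex(support.index).fillna(0.0)
        else:
            tie = pd.Series(0.0, index=support.index)
        ranked = pd.DataFrame({"support": support, "mean_abs_std_fc": tie})
        ranked = ranked.sort_values(
            by=["support", "mean_abs_std_fc"], ascending=[False, False], kind="mergesort"
        )
        out[direction] = ranked.head(top)
    return out


def overlap_percentage(query: set, reference: set) -> float:
    """Percent of the reference set also present in the query: 100 x / y."""
    if not reference:
        raise ValueError("reference set is empty")
    return 100.0 * len(set(query) & set(reference)) / len(reference)


# ---------------------------------------------------------------------------
# 3x3 cross-species direction contingency
# ---------------------------------------------------------------------------


@dataclass
class ContingencySummary:
    observed: pd.DataFrame  # 3x3 over (up, ns, down) x (up, ns, down)
    expected: pd.DataFrame
    adjusted_residuals: pd.DataFrame  # NaN where a margin is zero
    n: int


def contingency_adjusted_residuals(calls_a: pd.Series, calls_b: pd.Series) -> ContingencySummary:
    """Adjusted residuals of the species-A vs species-B direction table.

    Expected counts assume independence (row total x column total / n); the
    adjusted residual (O - E) / sqrt(E (1 - rowshare)(1 - colshare)) is
    approximately standard normal under independence, so |residual| > 3
    flags a cell as over- or under-populated. Cells in a zero row or column
    margin are undefined (NaN).
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call vectors differ in length")
    n = len(calls_a)
    if n < 9:
        raise ValueError("need at least 9 ortholog pairs")
    obs = np.zeros((3, 3))
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    for i, da in enumerate(_DIRECTIONS):
        for j, db in enumerate(_DIRECTIONS):
            obs[i, j] = np.sum((a == da) & (b == db))
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(expected * np.outer(1 - row / n, 1 - col / n))
        resid = (obs - expected) / denom
    resid[(np.outer(row, np.ones(3)) == 0) | (np.outer(np.ones(3), col) == 0)] = np.nan
    idx = pd.Index(_DIRECTIONS, name="species_a")
    cols = pd.Index(_DIRECTIONS, name="species_b")
    return ContingencySummary(
        observed=pd.DataFrame(obs, index=idx, columns=cols),
        expected=pd.DataFrame(expected, index=idx, columns=cols),
        adjusted_residuals=pd.DataFrame(resid, index=idx, columns=cols),
        n=n,
    )


# ---------------------------------------------------------------------------
# Rank-based and permutation enrichment
# ---------------------------------------------------------------------------


@dataclass
class RankEnrichmentResult:
    n_total: int
    n_foreground: int
    U: float
    z: float
    p: float
    cumulative_overlap: np.ndarray  # overlap count after each rank


def auc_rank_enrichment(ranked: list, foreground: set) -> RankEnrichmentResult:
    """Wilcoxon-Mann-Whitney statistic for foreground position in a ranking.

    ``ranked`` lists all N items best-first and must be duplicate-free; U
    counts, over foreground items, the background items ranked below them.
    Under a random foreground, z = (U - m(N-m)/2) / sqrt(m(N-m)(N+1)/12) is
    approximately standard normal; p is the upper tail (enrichment toward
    the top).
    """
    N = len(ranked)
    if len(set(ranked)) != N:
        raise ValueError("ranked list contains duplicates")
    foreground = set(foreground)
    m = len(foreground)
    if not 0 < m < N:
        raise ValueError("foreground must be a proper non-empty subset")
    if not foreground <= set(ranked):
        raise ValueError("foreground must be contained in the ranked list")
    is_fg = np.fromiter((item in foreground for item in ranked), dtype=bool, count=N)
    n_bg_below = np.cumsum(~is_fg[::-1])[::-1] - (~is_fg)  # background strictly below each rank
    U = float(n_bg_below[is_fg].sum())
    n_bg = N - m
    var = m * n_bg * (N + 1) / 12.0
    z = (U - m * n_bg / 2.0) / np.sqrt(var)
    p = float(stats.norm.sf(z))
    return RankEnrichmentResult(
        n_total=N, n_foreground=m, U=U, z=float(z), p=p, cumulative_overlap=np.cumsum(is_fg)
    )


@dataclass
class PermutationESResult:
    es: float
    null_es: np.ndarray
    percentile_95: float
    p: float


def permutation_enrichment_score(
    ranked: list,
    foreground: set,
    trials: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> PermutationESResult:
    """Running-sum enrichment score with a random-foreground null.

    The running sum gains 1/m at each foreground hit and loses 1/(N-m) at
    each miss; ES is its maximum (1.0 exactly when the foreground occupies
    the top m ranks). The null redraws m random foreground positions per
    trial; p = (1 + #null >= observed) / (trials + 1).
    """
    if trials < 100:
        raise ValueError("need at least 100 trials")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    N = len(ranked)
    foreground = set(foreground)
    m = len(foreground)
    if not 0 < m < N:
        raise ValueError("foreground must be a proper non-empty subset")
    is_fg = np.fromiter((item in foreground for item in ranked), dtype=bool, count=N)

    def es_of(mask: np.ndarray) -> float:
        # integer running sum scaled by m(N-m): exact, so a foreground
        # occupying the top m ranks yields ES = 1.0 precisely
        steps = np.where(mask, N - m, -m)
        return float(np.max(np.cumsum(steps))) / (m * (N - m))

    observed = es_of(is_fg)
    null = np.empty(trials)
    for t in range(trials):
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=m, replace=False)] = True
        null[t] = es_of(mask)
    p = (1.0 + float(np.sum(null >= observed))) / (trials + 1.0)
    return PermutationESResult(es=observed, null_es=null, percentile_95=float(np.percentile(null, 95)), p=p)


# ---------------------------------------------------------------------------
# Ortholog fold-change correlation
# ---------------------------------------------------------------------------


def correlate_orthologs(fc_a: np.ndarray, fc_b: np.ndarray) -> dict:
    """Pearson correlation of ortholog fold changes with central-region flags.

    Flags mark the 50% and 80% of points closest to the coordinate-wise
    median by Mahalanobis distance under the sample covariance (exactly
    ceil(0.5 n) and ceil(0.8 n) points).
    """
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if len(a) != len(b) or len(a) < 10:
        raise ValueError("need at least 10 paired finite values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one vector")
    r, p = stats.pearsonr(a, b)
    X = np.column_stack([a, b])
    center = np.median(X, axis=0)
    cov = np.cov(X, rowvar=False)
    inv = np.linalg.pinv(cov)  # pseudo-inverse tolerates degenerate clouds
    diff = X - center
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    order = np.argsort(d2, kind="mergesort")
    n = len(a)
    flags_50 = np.zeros(n, dtype=bool)
    flags_50[order[: int(np.ceil(0.5 * n))]] = True
    flags_80 = np.zeros(n, dtype=bool)
    flags_80[order[: int(np.ceil(0.8 * n))]] = True
    return {"r": float(r), "p": float(p), "central_50": flags_50, "central_80": flags_80, "mahalanobis_sq": d2}


def read_ortholog_map(path) -> pd.DataFrame:
    """Read a two-column 1:1 ortholog table; many-to-many rows are rejected."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    table.columns = ["gene_a", "gene_b"]
    dup_a = table["gene_a"].duplicated(keep=False)
    dup_b = table["gene_b"].duplicated(keep=False)
    bad = dup_a | dup_b
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows violate the 1:1 ortholog requirement")
    return table
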