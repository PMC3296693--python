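"""PWM scanning and motif-density association screens.

Scanning: every window on both strands is scored by summed log2
posterior/prior ratios; windows exceeding 90% of the motif's maximum score
are hits, and overlapping hits are collapsed greedily left-to-right into
non-overlapping matches, each counted once. Windows containing N are
skipped.

Screening: for each motif, a nested series of gene sets x_t (genes with at
least t matches in the -2000/+200 TSS window) is tested for bias in the
ratio of age-increased to age-decreased members (two-sided Fisher exact
against the transcriptome-wide split); motifs are ranked by the most
extreme proportion among sets holding at least 100 genes. Family-wise
significance uses a 2000-trial randomization of direction labels: P* is the
0.05 quantile of the null distribution of the minimum Fisher p over all
sets.

For variable-length region sets, motif density is measured as the Pearson
residual from a Poisson regression of match counts on ln(length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aging import adjust_bh
from .io import PWMRecord, Region

__all__ = [
    "encode_sequence",
    "estimate_background",
    "scan_hits",
    "scan_sequence",
    "count_window_matches",
    "ThresholdSeries",
    "build_threshold_series",
    "direction_bias_test",
    "screen_motifs",
    "SimCalibration",
    "two_sided_fisher_lookup",
    "calibrate_min_p",
    "score_length_adjusted",
    "sweep_foreground_contrast",
    "DEFAULT_MIN_SET_SIZE",
    "DEFAULT_N_TRIALS",
]

DEFAULT_MIN_SET_SIZE = 100
DEFAULT_N_TRIALS = 2000

_ENC_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC_TABLE[ord(_b)] = _i
    _ENC_TABLE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    return _ENC_TABLE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def estimate_background(sequences: list[str]) -> np.ndarray:
    """Empirical A/C/G/T frequencies over a set of sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases found")
    return counts / total


def _score_lut(score_matrix: np.ndarray) -> np.ndarray:
    """L x 5 lookup: column 4 (N) is -inf so N-containing windows never hit."""
    L = score_matrix.shape[0]
    lut = np.full((L, 5), -np.inf)
    lut[:, :4] = score_matrix
    return lut


def _window_scores(enc: np.ndarray, lut: np.ndarray) -> np.ndarray:
    L = lut.shape[0]
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.empty(0)
    total = lut[0, enc[:n_win]].copy()
    for j in range(1, L):
        total += lut[j, enc[j : j + n_win]]
    return total


def _reverse_complement_lut(lut: np.ndarray) -> np.ndarray:
    # position i on the reverse strand reads the complement of forward
    # position L-1-i; N stays N
    rc = lut[::-1][:, [3, 2, 1, 0, 4]]
    return rc


def scan_hits(sequence: str, pwm: PWMRecord, both_strands: bool = True) -> list[tuple[int, int]]:
    """Non-overlapping match intervals [start, end) after greedy collapse.

    Hit windows on either strand are pooled by their forward-coordinate
    interval, sorted by start, and collapsed left-to-right: a hit is kept
    only if it starts at or after the end of the last kept hit.
    """
    enc = encode_sequence(sequence)
    L = pwm.length
    if len(enc) < L:
        return []
    lut = _score_lut(pwm.score_matrix)
    starts = np.flatnonzero(_window_scores(enc, lut) > pwm.threshold)
    if both_strands:
        rc_starts = np.flatnonzero(_window_scores(enc, _reverse_complement_lut(lut)) > pwm.threshold)
        starts = np.union1d(starts, rc_starts)
    kept = []
    last_end = -1
    for s in starts:
        if s >= last_end:
            kept.append((int(s), int(s) + L))
            last_end = s + L
    return kept


def scan_sequence(sequence: str, pwm: PWMRecord, both_strands: bool = True) -> int:
    """Number of non-overlapping matches of ``pwm`` in ``sequence``."""
    return len(scan_hits(sequence, pwm, both_strands=both_strands))


def count_window_matches(
    regions: list[Region], pwms: list[PWMRecord], both_strands: bool = True
) -> pd.DataFrame:
    """Match-count table (genes x motifs) over one TSS window per gene.

    Window sequences are supplied 5'->3' of the linked gene, so minus-strand
    genes are handled identically to their plus-strand mirror. Duplicate
    gene windows are rejected.
    """
    windows = [r for r in regions if r.kind == "tss_window"]
    genes = [r.linked_gene for r in windows]
    if len(set(genes)) != len(genes):
        dup = pd.Series(genes).value_counts().idxmax()
        raise ValueError(f"duplicate TSS window for gene {dup!r}")
    counts = np.zeros((len(windows), len(pwms)), dtype=int)
    for j, pwm in enumerate(pwms):
        lut = _score_lut(pwm.score_matrix)
        rc_lut = _reverse_complement_lut(lut)
        L = pwm.length
        for i, region in enumerate(windows):
            enc = encode_sequence(region.sequence)
            if len(enc) < L:
                continue
            starts = np.flatnonzero(_window_scores(enc, lut) > pwm.threshold)
            if both_strands:
                rc = np.flatnonzero(_window_scores(enc, rc_lut) > pwm.threshold)
                starts = np.union1d(starts, rc)
            n = 0
            last_end = -1
            for s in starts:
                if s >= last_end:
                    n += 1
                    last_end = s + L
            counts[i, j] = n
    table = pd.DataFrame(counts, index=genes, columns=[p.motif_id for p in pwms])
    table.attrs["window"] = "tss_window"
    return table


# ---------------------------------------------------------------------------
# Threshold gene-set series
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSeries:
    """Nested gene sets x_t (>= t matches) for one motif, with bias tests."""

    motif_id: str
    table: pd.DataFrame  # per t: size, u, d, prop, p (q / passes_pstar filled later)
    rank_score: float  # most extreme |prop - 0.5| among sets with >= min genes
    empty: bool = False


def direction_bias_test(u: int, d: int, U: int, D: int) -> tuple[float, float]:
    """Two-sided Fisher test of a set's up/down split vs the background.

    Table [[u, d], [U-u, D-d]]; returns (p, proportion u/(u+d)).
    """
    if u + d < 1:
        raise ValueError("set has no directional genes")
    if U < u or D < d:
        raise ValueError("background totals smaller than set counts")
    p = float(stats.fisher_exact([[u, d], [U - u, D - d]], alternative="two-sided").pvalue)
    return p, u / (u + d)


def build_threshold_series(
    counts: pd.Series,
    directions: pd.Series,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    motif_id: str | None = None,
) -> ThresholdSeries:
    """Series of nested sets x_t = {genes with >= t matches}, t = 1..max.

    ``directions`` must cover the analyzed genes ({up, down, ns}); u_t and
    d_t count up/down members of each set and the Fisher test compares them
    to the direction totals over all analyzed genes. The motif's rank score
    is the most extreme proportion (distance from 0.5) among sets holding at
    least ``min_set_size`` genes.
    """
    counts = counts.loc[directions.index]
    motif_id = motif_id or (counts.name if counts.name else "motif")
    dir_arr = directions.to_numpy()
    U = int(np.sum(dir_arr == "up"))
    D = int(np.sum(dir_arr == "down"))
    cmax = int(counts.max()) if len(counts) else 0
    if cmax < 1:
        return ThresholdSeries(motif_id=str(motif_id), table=pd.DataFrame(columns=["t", "size", "u", "d", "prop", "p"]), rank_score=float("nan"), empty=True)
    records = []
    cvals = counts.to_numpy()
    for t in range(1, cmax + 1):
        in_set = cvals >= t
        size = int(in_set.sum())
        u = int(np.sum(in_set & (dir_arr == "up")))
        d = int(np.sum(in_set & (dir_arr == "down")))
        if u + d >= 1:
            p, prop = direction_bias_test(u, d, U, D)
        else:
            p, prop = float("nan"), float("nan")
        records.append({"t": t, "size": size, "u": u, "d": d, "prop": prop, "p": p})
    table = pd.DataFrame(records)
    eligible = table[(table["size"] >= min_set_size) & np.isfinite(table["prop"])]
    rank_score = float(np.max(np.abs(eligible["prop"] - 0.5))) if len(eligible) else float("nan")
    return ThresholdSeries(motif_id=str(motif_id), table=table, rank_score=rank_score)


def screen_motifs(
    count_table: pd.DataFrame,
    directions: pd.Series,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Threshold-series screen over every motif of a count table.

    Returns the concatenated per-set table (motif, t, size, u, d, prop, p)
    with BH-adjusted q computed across all sets of all motifs, plus each
    motif's rank score. Genes lacking a direction call still belong to sets
    but contribute to neither u nor d.
    """
    directions = directions.loc[count_table.index]
    frames = []
    for motif_id in count_table.columns:
        series = build_threshold_series(count_table[motif_id], directions, min_set_size=min_set_size, motif_id=motif_id)
        if series.empty:
            continue
        tbl = series.table.copy()
        tbl.insert(0, "motif", motif_id)
        tbl["rank_score"] = series.rank_score
        frames.append(tbl)
    if not frames:
        return pd.DataFrame(columns=["motif", "t", "size", "u", "d", "prop", "p", "q", "rank_score"])
    out = pd.concat(frames, ignore_index=True)
    tested = np.isfinite(out["p"].to_numpy(dtype=float))
    q = np.full(len(out), np.nan)
    q[tested] = adjust_bh(out.loc[tested, "p"].to_numpy(dtype=float))
    out["q"] = q
    return out


# ---------------------------------------------------------------------------
# Simulation-based family-wise calibration
# ---------------------------------------------------------------------------


@dataclass
class SimCalibration:
    n_trials: int
    min_p: np.ndarray  # one minimum Fisher p per trial
    p_star: float  # 0.05 quantile of the min-p distribution


def two_sided_fisher_lookup(set_size: int, U: int, D: int) -> np.ndarray:
    """Two-sided Fisher p for every possible up-count u = 0..set_size.

    The table [[u, s-u], [U-u, D-(s-u)]] has fixed margins, so u follows a
    hypergeometric law; the two-sided p sums the probabilities of all
    outcomes no more likely than the observed one (matching the exact-test
    convention with a 1 + 1e-7 tie guard). Entries outside the support are
    set to NaN.
    """
    N = U + D
    s = set_size
    u_all = np.arange(s + 1)
    pmf = stats.hypergeom.pmf(u_all, N, U, s)
    support = (u_all >= max(0, s - D)) & (u_all <= min(s, U))
    out = np.full(s + 1, np.nan)
    sp = pmf[support]
    for u in u_all[support]:
        out[u] = min(1.0, float(sp[sp <= pmf[u] * (1 + 1e-7)].sum()))
    return out


def calibrate_min_p(
    memberships: np.ndarray,
    up_labels: np.ndarray,
    n_trials: int = DEFAULT_N_TRIALS,
    rng: np.random.Generator | int | None = None,
    quantile: float = 0.05,
) -> SimCalibration:
    """Null distribution of the minimum Fisher p over a family of gene sets.

    ``memberships`` is a boolean genes x sets matrix over the directional
    genes of a run (set sizes stay fixed at their observed values);
    ``up_labels`` is the observed boolean up/down assignment. Each trial
    permutes the direction labels over genes — equivalent under
    exchangeability to randomly re-assigning genes to sets, while preserving
    both the set sizes and the direction totals — recomputes every set's
    two-sided Fisher p, and records the minimum. P* is the ``quantile``
    (default 0.05) point of that null sample.
    """
    if n_trials < 100:
        raise ValueError("n_trials below 100 makes the quantile unstable")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    memberships = np.asarray(memberships, dtype=bool)
    up_labels = np.asarray(up_labels, dtype=bool)
    n_genes, n_sets = memberships.shape
    if up_labels.shape != (n_genes,):
        raise ValueError("labels and memberships disagree on gene count")
    U = int(up_labels.sum())
    D = n_genes - U
    sizes = memberships.sum(axis=0)
    lookups = {int(s): two_sided_fisher_lookup(int(s), U, D) for s in np.unique(sizes)}

    perms = rng.permuted(np.tile(up_labels, (n_trials, 1)), axis=1)
    u_mat = perms.astype(np.float32) @ memberships.astype(np.float32)  # trials x sets
    u_mat = np.rint(u_mat).astype(int)
    p_mat = np.empty((n_trials, n_sets))
    for j in range(n_sets):
        p_mat[:, j] = lookups[int(sizes[j])][u_mat[:, j]]
    min_p = np.nanmin(p_mat, axis=1)
    p_star = float(np.quantile(min_p, quantile))
    return SimCalibration(n_trials=n_trials, min_p=min_p, p_star=p_star)


def family_from_screen(
    count_table: pd.DataFrame, directions: pd.Series
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Set-membership matrix over directional genes for min-p calibration.

    The family comprises every threshold set of every motif in the run,
    restricted to genes with an up or down call (others cannot shift any
    set's Fisher table). Returns (memberships, up_labels, set index table).
    """
    directions = directions.loc[count_table.index]
    directional = directions.isin(["up", "down"]).to_numpy()
    up_labels = (directions.to_numpy() == "up")[directional]
    cols = []
    index_rows = []
    for motif_id in count_table.columns:
        cvals = count_table[motif_id].to_numpy()[directional]
        cmax = int(cvals.max()) if len(cvals) else 0
        for t in range(1, cmax + 1):
            member = cvals >= t
            if member.sum() == 0:
                continue
            cols.append(member)
            index_rows.append({"motif": motif_id, "t": t})
    if not cols:
        raise ValueError("no non-empty sets in the family")
    memberships = np.column_stack(cols)
    return memberships, up_labels, pd.DataFrame(index_rows)


# ---------------------------------------------------------------------------
# Length-adjusted residual scores
# ---------------------------------------------------------------------------


def score_length_adjusted(
    lengths: np.ndarray, counts: np.ndarray, residual_type: str = "pearson"
) -> pd.DataFrame:
    """Length-free motif-density scores via Poisson regression on ln(length).

    Fits a log-link Poisson model of match counts on ln(length); the score
    is the Pearson residual (y - mu) / sqrt(mu) by default (deviance
    residuals by flag). Positive scores mean more matches than expected for
    the sequence's length.
    """
    lengths = np.asarray(lengths, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(lengths) < 50:
        raise ValueError("need at least 50 regions")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    X = sm.add_constant(np.log(lengths))
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    result = model.fit()
    if not result.converged:
        raise RuntimeError(f"Poisson regression did not converge: {result.summary()}")
    mu = result.fittedvalues
    if residual_type == "pearson":
        score = (counts - mu) / np.sqrt(mu)
    elif residual_type == "deviance":
        score = result.resid_deviance
    else:
        raise ValueError("residual_type must be 'pearson' or 'deviance'")
    out = pd.DataFrame({"count": counts, "length": lengths, "score": score})
    out.attrs["coef"] = {"intercept": float(result.params[0]), "ln_length": float(result.params[1])}
    return out


def sweep_foreground_contrast(
    scores: pd.Series,
    region_gene: pd.Series,
    ranked_genes: list[str],
    k_grid: list[int] | None = None,
) -> pd.DataFrame:
    """Foreground-vs-background mean residual scores over a selectivity sweep.

    ``ranked_genes`` are one direction's genes ordered by ascending aging p
    (most strongly age-regulated first). For each k in the grid, the
    foreground holds regions linked to the top-k genes and the background
    all other scored regions; normal-approximation 95% confidence intervals
    are placed on both means and a k is significant when the intervals are
    disjoint. A k with an empty background is flagged degenerate.
    """
    if k_grid is None:
        top = len(ranked_genes)
        k_grid = sorted(set(np.linspace(min(100, top), top, num=min(10, top), dtype=int).tolist()))
    records = []
    score_genes = region_gene.loc[scores.index]
    for k in k_grid:
        if k > len(ranked_genes):
            k = len(ranked_genes)
        fg_genes = set(ranked_genes[:k])
        fg_mask = score_genes.isin(fg_genes).to_numpy()
        fg = scores.to_numpy()[fg_mask]
        bg = scores.to_numpy()[~fg_mask]
        degenerate = len(bg) == 0 or len(fg) == 0
        def ci(x: np.ndarray) -> tuple[float, float, float]:
            if len(x) == 0:
                return (float("nan"),) * 3
            m = float(np.mean(x))
            half = 1.96 * float(np.std(x, ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else float("inf")
            return m, m - half, m + half
        fg_mean, fg_lo, fg_hi = ci(fg)
        bg_mean, bg_lo, bg_hi = ci(bg)
        significant = (not degenerate) and (fg_lo > bg_hi or fg_hi < bg_lo)
        records.append(
            {
                "k": int(k),
                "n_foreground": int(len(fg)),
                "n_background": int(len(bg)),
                "fg_mean": fg_mean,
                "fg_lo": fg_lo,
                "fg_hi": fg_hi,
                "bg_mean": bg_mean,
                "bg_lo": bg_lo,
                "bg_hi": bg_hi,
                "significant": bool(significant),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(records).drop_duplicates(subset="k").reset_index(drop=True)
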