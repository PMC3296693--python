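"""In-silico inflammation profiling of cell-type abundance shifts.

Each cell population is summarized by its signature transcripts (the
transcripts most elevated in that population relative to a heterogeneous
tissue reference). In an aging contrast, n1 counts signature transcripts
with old/young fold change above 1 and n2 those below 1; a directional bias
of n1 vs n2 relative to the transcriptome-wide split signals increased (or
decreased) abundance of the population with age. Exclusion-adjusted counts
(n1*, n2*) guard against shared markers: a population's members are dropped
if they are also signature transcripts of another population with a
strictly larger raw n1/n2 ratio. A population is called significant only
when both the raw and the adjusted counts are biased (BH-adjusted Fisher
p < 0.05 in the same direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aging import adjust_bh
from .io import ExpressionStudy
from .simulate import CompendiumPanel

__all__ = [
    "SignatureSet",
    "derive_signature_set",
    "derive_all_signatures",
    "compute_signature_counts",
    "adjust_signature_counts",
    "profile_populations",
    "aggregate_category_display",
    "signature_age_trajectory",
]

DEFAULT_SIGNATURE_SIZE = 500


@dataclass
class SignatureSet:
    population_id: str
    category: str
    members: list[str]
    t_stats: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    truncated: bool = False  # fewer positive-effect candidates than requested

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"{self.population_id}: duplicate signature members")


def derive_signature_set(
    panel: CompendiumPanel, population_id: str, n: int = DEFAULT_SIGNATURE_SIZE
) -> SignatureSet:
    """Top-``n`` transcripts elevated in a population vs the reference panel.

    Candidates are transcripts with a positive population-minus-reference
    effect, ranked by two-sample t statistic descending. When fewer than
    ``n`` candidates exist, the set is truncated and flagged.
    """
    rep_cols = panel.populations[population_id]
    if len(rep_cols) < 2:
        raise ValueError("population needs at least 2 replicates")
    if len(panel.reference_cols) < 10:
        raise ValueError("reference panel needs at least 10 columns")
    pop = panel.values[rep_cols].to_numpy()
    ref = panel.values[panel.reference_cols].to_numpy()
    with warnings.catch_warnings():
        # zero-variance transcripts yield nan t statistics and are filtered
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(pop, ref, axis=1)
    effect = pop.mean(axis=1) - ref.mean(axis=1)
    t = pd.Series(t, index=panel.values.index)
    candidates = t[(effect > 0) & np.isfinite(t)].sort_values(ascending=False)
    members = list(candidates.index[:n])
    return SignatureSet(
        population_id=population_id,
        category=panel.categories.get(population_id, population_id),
        members=members,
        t_stats=candidates.iloc[: len(members)],
        truncated=len(members) < n,
    )


def derive_all_signatures(panel: CompendiumPanel, n: int = DEFAULT_SIGNATURE_SIZE) -> list[SignatureSet]:
    return [derive_signature_set(panel, pop, n=n) for pop in panel.populations]


@dataclass
class SignatureCounts:
    n1: int  # members with age-increased expression (fc > 1)
    n2: int  # members with age-decreased expression (fc < 1)
    n_missing: int  # members absent from the profile
    n_tied: int  # members with fc exactly 1 (counted in neither)
    mean_percent_change: float

    @property
    def p_hat(self) -> float:
        total = self.n1 + self.n2
        return self.n1 / total if total else float("nan")

    @property
    def ratio(self) -> float:
        if self.n2 == 0:
            return float("inf") if self.n1 else float("nan")
        return self.n1 / self.n2


def compute_signature_counts(
    members: list[str], profile: pd.DataFrame, significance_filter: bool = False, alpha: float = 0.05
) -> SignatureCounts:
    """Directional counts of a signature's members in an aging profile.

    By default every member counts by the sign of its fold-change estimate;
    with ``significance_filter`` only members with p < alpha contribute.
    Members with fc exactly 1 contribute to neither count.
    """
    present = [m for m in members if m in profile.index]
    n_missing = len(members) - len(present)
    sub = profile.loc[present]
    fc = sub["fc"].to_numpy(dtype=float)
    usable = np.isfinite(fc)
    if significance_filter:
        usable &= sub["p"].to_numpy() < alpha
    n1 = int(np.sum(usable & (fc > 1)))
    n2 = int(np.sum(usable & (fc < 1)))
    n_tied = int(np.sum(usable & (fc == 1)))
    mean_pct = float(np.mean(100.0 * (fc[usable] - 1.0))) if usable.any() else float("nan")
    return SignatureCounts(n1=n1, n2=n2, n_missing=n_missing, n_tied=n_tied, mean_percent_change=mean_pct)


def adjust_signature_counts(
    signatures: list[SignatureSet],
    profile: pd.DataFrame,
    significance_filter: bool = False,
) -> dict[str, tuple[SignatureCounts, SignatureCounts, list[str]]]:
    """Raw and exclusion-adjusted counts for every population.

    For population i, members also present in any other population's
    signature with a strictly larger raw n1/n2 ratio are dropped before the
    adjusted counts are recomputed; ties leave both sets intact, so the
    population with the single largest raw ratio is never altered.
    Returns population -> (raw counts, adjusted counts, surviving members).
    """
    raw = {
        s.population_id: compute_signature_counts(s.members, profile, significance_filter=significance_filter)
        for s in signatures
    }
    member_sets = {s.population_id: set(s.members) for s in signatures}
    out = {}
    for s in signatures:
        mine = raw[s.population_id].p_hat
        dominated_by = [
            other
            for other in member_sets
            if other != s.population_id
            and np.isfinite(raw[other].p_hat)
            and np.isfinite(mine)
            and raw[other].p_hat > mine
        ]
        survivors = [m for m in s.members if not any(m in member_sets[o] for o in dominated_by)]
        adj = compute_signature_counts(survivors, profile, significance_filter=significance_filter)
        out[s.population_id] = (raw[s.population_id], adj, survivors)
    return out


def _fisher_one_sided(n1: int, n2: int, U: int, D: int, alternative: str) -> float:
    if U - n1 < 0 or D - n2 < 0:
        raise ValueError("signature counts exceed background totals")
    table = [[n1, n2], [U - n1, D - n2]]
    return float(stats.fisher_exact(table, alternative=alternative).pvalue)


def profile_populations(
    signatures: list[SignatureSet],
    profile: pd.DataFrame,
    significance_filter: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full abundance-shift screen over all populations of one aging profile.

    The background totals U and D are the up/down counts among all analyzed
    transcripts in the profile. Increase and decrease are tested as two
    one-sided Fisher families (raw and exclusion-adjusted counts each),
    BH-adjusted across populations within a family; a population is
    significant when both its raw and adjusted q fall below ``alpha`` on the
    same side.
    """
    fc = profile["fc"].to_numpy(dtype=float)
    usable = np.isfinite(fc)
    if significance_filter:
        usable &= profile["p"].to_numpy() < alpha
    U = int(np.sum(usable & (fc > 1)))
    D = int(np.sum(usable & (fc < 1)))

    counts = adjust_signature_counts(signatures, profile, significance_filter=significance_filter)
    rows = []
    p_inc_raw, p_dec_raw, p_inc_star, p_dec_star = [], [], [], []
    for s in signatures:
        raw, adj, survivors = counts[s.population_id]
        p_inc_raw.append(_fisher_one_sided(raw.n1, raw.n2, U, D, "greater"))
        p_dec_raw.append(_fisher_one_sided(raw.n1, raw.n2, U, D, "less"))
        p_inc_star.append(_fisher_one_sided(adj.n1, adj.n2, U, D, "greater"))
        p_dec_star.append(_fisher_one_sided(adj.n1, adj.n2, U, D, "less"))
        rows.append((s, raw, adj))
    q_inc_raw = adjust_bh(p_inc_raw)
    q_dec_raw = adjust_bh(p_dec_raw)
    q_inc_star = adjust_bh(p_inc_star)
    q_dec_star = adjust_bh(p_dec_star)

    records = []
    for i, (s, raw, adj) in enumerate(rows):
        sig_inc = q_inc_raw[i] < alpha and q_inc_star[i] < alpha
        sig_dec = q_dec_raw[i] < alpha and q_dec_star[i] < alpha
        if sig_inc:
            direction = "increase"
        elif sig_dec:
            direction = "decrease"
        else:
            direction = "none"
        increase_side = not (np.isfinite(raw.p_hat) and raw.p_hat < 0.5)
        records.append(
            {
                "population": s.population_id,
                "category": s.category,
                "n1": raw.n1,
                "n2": raw.n2,
                "n1_star": adj.n1,
                "n2_star": adj.n2,
                "p_hat": raw.p_hat,
                "p_hat_star": adj.p_hat,
                "mean_percent_change": raw.mean_percent_change,
                "p_raw": p_inc_raw[i] if increase_side else p_dec_raw[i],
                "p_star": p_inc_star[i] if increase_side else p_dec_star[i],
                "q_raw": q_inc_raw[i] if increase_side else q_dec_raw[i],
                "q_star": q_inc_star[i] if increase_side else q_dec_star[i],
                "significant": sig_inc or sig_dec,
                "direction": direction,
            }
        )
    return pd.DataFrame(records).set_index("population")


def aggregate_category_display(category_results: pd.DataFrame) -> dict:
    """Chart cell for one category: which population's proportion is shown.

    The maximum p-hat is displayed when the median p-hat across the
    category's populations exceeds 0.5, otherwise the minimum; the marker is
    increase/decrease when the displayed population is significant in that
    direction.
    """
    if len(category_results) == 0:
        raise ValueError("category has no populations")
    p_hats = category_results["p_hat"]
    if np.median(p_hats) > 0.5:
        shown = p_hats.idxmax()
    else:
        shown = p_hats.idxmin()
    row = category_results.loc[shown]
    marker = row["direction"] if row["significant"] else "none"
    return {
        "displayed_population": shown,
        "displayed_proportion": float(row["p_hat"]),
        "marker": marker,
    }


def signature_age_trajectory(
    members: list[str], study: ExpressionStudy, n_bins: int = 4, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Median and IQR of member-wise expression ratios per age group.

    Samples are binned by age (quantile bins by default). For each member
    transcript, the ratio is the group mean on the absolute scale divided by
    the youngest group's mean; the youngest group's ratio is identically 1.
    Empty groups are dropped with a warning.
    """
    ages = study.ages.to_numpy(dtype=float)
    if bin_edges is None:
        bin_edges = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
        bin_edges[-1] += 1e-9
    labels = np.digitize(ages, bin_edges[1:-1])
    present = [m for m in members if m in study.values.index]
    A = np.exp2(study.values.loc[present].to_numpy())

    group_means = {}
    for g in range(len(bin_edges) - 1):
        mask = labels == g
        if mask.sum() == 0:
            warnings.warn(f"age group {g} has no samples; dropped")
            continue
        group_means[g] = A[:, mask].mean(axis=1)
    groups = sorted(group_means)
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty age groups")
    base = group_means[groups[0]]
    records = []
    for g in groups:
        ratio = group_means[g] / base
        records.append(
            {
                "group": g,
                "age_mean": float(ages[labels == g].mean()),
                "n_samples": int((labels == g).sum()),
                "median_ratio": float(np.median(ratio)),
                "q1": float(np.percentile(ratio, 25)),
                "q3": float(np.percentile(ratio, 75)),
            }
        )
    return pd.DataFrame(records)
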