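"""Synthetic-data generators with planted, recoverable ground truth.

Every generator is a pure function of its configuration and seed, and each
returns a truth table sufficient to score recovery or power downstream
without re-reading the configuration. The generators emulate the
distributions the analyses assume: log2 expression linear in age with
Gaussian noise, cell-population panels with elevated signature transcripts,
promoter windows with planted motif occurrences whose rate depends on the
gene's aging direction, and multi-study collections with partially shared
or discordant signatures across two species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionStudy, PWMRecord, Region

__all__ = [
    "SimulationConfig",
    "CompendiumPanel",
    "StudyCollection",
    "simulate_aging_study",
    "simulate_reference_compendium",
    "simulate_mixture_aging_study",
    "simulate_motif_regions",
    "make_pwm_collection",
    "simulate_ontology",
    "simulate_study_collection",
]

DEFAULT_SEED = 20120307
PLANTED_CONSENSUS = "GCCACGTGAC"  # non-palindromic; decoys share its length
_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class SimulationConfig:
    """Study conditions for all generators.

    Defaults mirror the study designs the analyses target: a continuous-age
    human-like cohort of 60 subjects aged 18-75 years, mouse-like two-group
    designs with 5 young (5 mo) and 5 old (30 mo) animals per run,
    500-transcript cell-population signatures over a 10,000-gene
    transcriptome (so one signature is a small fraction of the whole, as on
    the arrays these methods target), a -2000/+200 TSS scan window and
    planted motif-occurrence rates of 3 vs 1 per window.
    """

    seed: int = DEFAULT_SEED
    n_genes: int = 10000
    n_samples: int = 60
    age_range: tuple[float, float] = (18.0, 75.0)  # years, continuous design
    young_age: float = 5.0  # months, two-group design
    old_age: float = 30.0
    n_per_group: int = 5
    effect_fraction: float = 0.2
    slope_sd: float = 0.02  # log2 per age unit
    noise_sd: float = 0.2  # residual sd, log2 units
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    baseline_range: tuple[float, float] = (6.0, 12.0)
    # reference compendium
    n_populations: int = 4
    replicates_per_population: int = 3
    n_reference: int = 12
    signature_size: int = 500
    signature_delta: float = 2.0
    mixing_shift: float = 0.3
    # motif regions
    lambda_up: float = 3.0
    lambda_down: float = 1.0
    lambda_bg: float = 1.0
    window_up: int = 2000
    window_down: int = 200
    n_decoys: int = 20
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # study collections
    n_profiles: int = 4
    shared_core_fraction: float = 0.1
    discordant_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("effect_fraction", "outlier_fraction", "shared_core_fraction", "discordant_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.shared_core_fraction + self.discordant_fraction > 1:
            raise ValueError("core and discordant fractions sum above 1")
        for name in ("slope_sd", "noise_sd", "lambda_up", "lambda_down", "lambda_bg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if not np.isclose(sum(self.base_freqs), 1.0):
            raise ValueError("base_freqs must sum to 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Aging studies
# ---------------------------------------------------------------------------


def simulate_aging_study(
    config: SimulationConfig,
    design: str = "continuous_age",
    species_tag: str = "human",
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate log2 expression linear in age: y = a + b*age + N(0, noise_sd).

    A fraction ``effect_fraction`` of genes receives a nonzero planted slope
    drawn from N(0, slope_sd); optional outlier cells are shifted by
    ``outlier_shift`` to exercise the robust fit. Returns the study and a
    truth table with one row per gene (``truth_slope``).
    """
    rng = _rng(config, rng)
    genes = _gene_ids(config.n_genes)
    if design == "continuous_age":
        if config.n_samples < 4:
            raise ValueError("continuous design requires at least 4 samples")
        ages = rng.uniform(*config.age_range, size=config.n_samples)
        group = None
        age_unit = "years"
        n = config.n_samples
    elif design == "two_group":
        n = 2 * config.n_per_group
        if config.n_per_group < 2:
            raise ValueError("two-group design requires at least 2 per group")
        ages = np.r_[np.full(config.n_per_group, config.young_age), np.full(config.n_per_group, config.old_age)]
        group = np.r_[["young"] * config.n_per_group, ["old"] * config.n_per_group]
        age_unit = "months"
    else:
        raise ValueError(f"unknown design {design!r}")
    samples = [f"s{i + 1:03d}" for i in range(n)]
    sex = np.array(["F", "M"] * ((n + 1) // 2))[:n]

    slopes = np.zeros(config.n_genes)
    n_effect = int(round(config.effect_fraction * config.n_genes))
    effect_idx = rng.choice(config.n_genes, size=n_effect, replace=False)
    slopes[effect_idx] = rng.normal(0.0, config.slope_sd, size=n_effect)
    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
    Y = baseline[:, None] + slopes[:, None] * ages[None, :] + rng.normal(0.0, config.noise_sd, (config.n_genes, n))
    if config.outlier_fraction > 0:
        mask = rng.random((config.n_genes, n)) < config.outlier_fraction
        Y = Y + mask * config.outlier_shift

    study = ExpressionStudy(
        values=pd.DataFrame(Y, index=genes, columns=samples),
        ages=pd.Series(ages, index=samples),
        sex=pd.Series(sex, index=samples),
        species_tag=species_tag,
        design=design,
        group=None if group is None else pd.Series(group, index=samples),
        age_unit=age_unit,
    )
    truth = pd.DataFrame({"gene": genes, "truth_slope": slopes})
    return study, truth


# ---------------------------------------------------------------------------
# Reference compendium and abundance mixing
# ---------------------------------------------------------------------------

_POP_NAMES = [
    "cd4_t_cell",
    "cd8_t_cell",
    "dendritic_cell",
    "macrophage",
    "nk_cell",
    "b_cell",
    "neutrophil",
    "mast_cell",
]
_POP_CATEGORIES = {
    "cd4_t_cell": "T-cell",
    "cd8_t_cell": "T-cell",
    "dendritic_cell": "dendritic cell",
    "macrophage": "myeloid",
    "nk_cell": "NK cell",
    "b_cell": "B-cell",
    "neutrophil": "myeloid",
    "mast_cell": "mast cell",
}


@dataclass
class CompendiumPanel:
    """Cell-population replicate columns plus heterogeneous reference columns."""

    values: pd.DataFrame  # genes x columns, log2
    populations: dict[str, list[str]]  # population -> replicate columns
    reference_cols: list[str]
    categories: dict[str, str]
    truth_signatures: dict[str, list[str]] = field(default_factory=dict)
    baseline: pd.Series | None = None


def simulate_reference_compendium(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CompendiumPanel:
    """Panel with ``signature_size`` planted high-expression genes per population.

    Planted signature genes are elevated by ``signature_delta`` log2 units in
    their population's replicate columns over the reference baseline.
    """
    rng = _rng(config, rng)
    if config.signature_size > config.n_genes:
        raise ValueError("signature_size exceeds n_genes")
    if config.replicates_per_population < 2:
        raise ValueError("need at least 2 replicates per population")
    if config.n_reference < 10:
        raise ValueError("need at least 10 reference columns")
    genes = _gene_ids(config.n_genes)
    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
    pops = [_POP_NAMES[i % len(_POP_NAMES)] if i < len(_POP_NAMES) else f"pop{i + 1}" for i in range(config.n_populations)]

    cols: dict[str, np.ndarray] = {}
    populations: dict[str, list[str]] = {}
    truth: dict[str, list[str]] = {}
    for pop in pops:
        sig_idx = rng.choice(config.n_genes, size=config.signature_size, replace=False)
        elevation = np.zeros(config.n_genes)
        elevation[sig_idx] = config.signature_delta
        truth[pop] = [genes[i] for i in sorted(sig_idx)]
        rep_cols = []
        for r in range(config.replicates_per_population):
            name = f"{pop}_rep{r + 1}"
            cols[name] = baseline + elevation + rng.normal(0.0, config.noise_sd, config.n_genes)
            rep_cols.append(name)
        populations[pop] = rep_cols
    ref_cols = []
    for r in range(config.n_reference):
        name = f"ref{r + 1:02d}"
        cols[name] = baseline + rng.normal(0.0, config.noise_sd, config.n_genes)
        ref_cols.append(name)

    values = pd.DataFrame(cols, index=genes)
    categories = {p: _POP_CATEGORIES.get(p, p) for p in pops}
    return CompendiumPanel(
        values=values,
        populations=populations,
        reference_cols=ref_cols,
        categories=categories,
        truth_signatures=truth,
        baseline=pd.Series(baseline, index=genes),
    )


def simulate_mixture_aging_study(
    config: SimulationConfig,
    panel: CompendiumPanel,
    targets: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Two-group study whose old samples up-weight target populations' markers.

    Each target population's planted signature genes are multiplied by
    (1 + shift) on the absolute scale in old samples (a stand-in for
    increased abundance or infiltration of that cell population with aging);
    all other genes carry no planted change. Returns the study and a truth
    table of (population, shift).
    """
    rng = _rng(config, rng)
    if targets is None:
        first = next(iter(panel.populations))
        targets = {first: config.mixing_shift}
    for pop, shift in targets.items():
        if pop not in panel.truth_signatures:
            raise ValueError(f"unknown target population {pop!r}")
        if not -1 < shift < 5:
            raise ValueError("mixing shift must lie in (-1, 5)")
    genes = list(panel.values.index)
    n_genes = len(genes)
    baseline = panel.baseline.to_numpy() if panel.baseline is not None else panel.values[panel.reference_cols].mean(axis=1).to_numpy()

    shift_log2 = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for pop, shift in targets.items():
        idx = [gene_pos[g] for g in panel.truth_signatures[pop]]
        shift_log2[idx] = np.log2(1.0 + shift)

    n = 2 * config.n_per_group
    samples = [f"s{i + 1:03d}" for i in range(n)]
    group = np.r_[["young"] * config.n_per_group, ["old"] * config.n_per_group]
    ages = np.r_[np.full(config.n_per_group, config.young_age), np.full(config.n_per_group, config.old_age)]
    old = group == "old"
    Y = baseline[:, None] + shift_log2[:, None] * old[None, :] + rng.normal(0.0, config.noise_sd, (n_genes, n))
    study = ExpressionStudy(
        values=pd.DataFrame(Y, index=genes, columns=samples),
        ages=pd.Series(ages, index=samples),
        sex=pd.Series(np.array(["F", "M"] * ((n + 1) // 2))[:n], index=samples),
        species_tag="mixture",
        design="two_group",
        group=pd.Series(group, index=samples),
        age_unit="months",
    )
    truth = pd.DataFrame({"population": list(targets), "truth_shift": [targets[p] for p in targets]})
    return study, truth


# ---------------------------------------------------------------------------
# Motif regions
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, freqs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=freqs)


def _find_exact(arr: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Start offsets of exact occurrences of ``pattern`` in ``arr``."""
    L = len(pattern)
    if len(arr) < L:
        return np.empty(0, dtype=int)
    hits = np.ones(len(arr) - L + 1, dtype=bool)
    for j, b in enumerate(pattern):
        hits &= arr[j : j + len(hits)] == b
    return np.flatnonzero(hits)


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def simulate_motif_regions(
    config: SimulationConfig,
    directions: pd.Series,
    consensus: str = PLANTED_CONSENSUS,
    length_range: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Region], pd.Series]:
    """TSS windows with planted consensus occurrences at direction-linked rates.

    Each gene's occurrence count is Poisson with mean lambda_up, lambda_down
    or lambda_bg according to its direction label; background sequence is
    regenerated (rejection) until it is free of chance consensus matches on
    either strand, so planted counts are exact. Occurrences are embedded
    non-overlapping at uniform positions, each on a random strand. With
    ``length_range`` set, region lengths vary and rates scale proportionally
    to length (for length-adjustment tests).
    """
    rng = _rng(config, rng)
    freqs = np.asarray(config.base_freqs)
    pat_f = _encode(consensus)
    pat_r = _encode(_revcomp(consensus))
    L = len(consensus)
    window_len = config.window_up + config.window_down
    lam_by_dir = {"up": config.lambda_up, "down": config.lambda_down, "ns": config.lambda_bg}

    regions: list[Region] = []
    truth_counts = {}
    for gene, direction in directions.items():
        length = window_len if length_range is None else int(rng.integers(length_range[0], length_range[1] + 1))
        lam = lam_by_dir[str(direction)] * (1.0 if length_range is None else length / window_len)
        count = int(rng.poisson(lam))
        if count * L > length:
            raise ValueError(f"window of {length} bp too short to host {count} occurrences")
        for _ in range(200):
            arr = _random_seq(rng, length, freqs)
            # place non-overlapping occurrences
            placed: list[int] = []
            ok = True
            for _k in range(count):
                for _try in range(200):
                    start = int(rng.integers(0, length - L + 1))
                    if all(start + L <= p or start >= p + L for p in placed):
                        placed.append(start)
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            for start in placed:
                pat = pat_f if rng.random() < 0.5 else pat_r
                arr[start : start + L] = pat
            found = np.union1d(_find_exact(arr, pat_f), _find_exact(arr, pat_r))
            if len(found) == count and set(found.tolist()) == set(placed):
                break
        else:  # pragma: no cover - rejection virtually always succeeds
            raise RuntimeError(f"could not build a clean region for gene {gene}")
        seq = "".join(_BASES[arr])
        regions.append(Region(region_id=f"win_{gene}", sequence=seq, kind="tss_window", linked_gene=str(gene), strand="+"))
        truth_counts[str(gene)] = count
    return regions, pd.Series(truth_counts, name="truth_count")


def make_pwm_collection(
    config: SimulationConfig,
    consensus: str = PLANTED_CONSENSUS,
    rng: np.random.Generator | None = None,
) -> list[PWMRecord]:
    """The planted near-consensus motif plus ``n_decoys`` random decoys.

    All motifs are sharp position-probability models (one dominant base per
    position) of the same length, so only exact consensus matches exceed the
    90%-of-max score threshold.
    """
    rng = _rng(config, rng)
    background = np.asarray(config.base_freqs)

    def sharp(motif_id: str, cons: str) -> PWMRecord:
        probs = np.full((len(cons), 4), 0.0)
        for i, b in enumerate(cons):
            probs[i, "ACGT".index(b)] = 1.0
        return PWMRecord.from_counts(motif_id, probs, background)

    records = [sharp("planted", consensus)]
    seen = {consensus, _revcomp(consensus)}
    i = 0
    while len(records) < config.n_decoys + 1:
        cons = "".join(_BASES[_random_seq(rng, len(consensus), background)])
        if cons in seen or _revcomp(cons) in seen:
            continue
        seen.update({cons, _revcomp(cons)})
        i += 1
        records.append(sharp(f"decoy{i:02d}", cons))
    return records


# ---------------------------------------------------------------------------
# Toy ontology
# ---------------------------------------------------------------------------


def simulate_ontology(
    config: SimulationConfig,
    genes: list[str],
    n_branches: int = 5,
    n_leaves_per_branch: int = 4,
    leaf_size: int = 25,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A three-level toy term DAG with random gene annotations.

    One root, ``n_branches`` intermediate terms, and ``n_leaves_per_branch``
    leaves per branch; each leaf annotates ``leaf_size`` random genes.
    Returns (term_parent, term_gene) two-column tables.
    """
    rng = _rng(config, rng)
    parents = []
    annotations = []
    for b in range(n_branches):
        branch = f"T{b + 1:03d}"
        parents.append({"term": branch, "parent": "T000"})
        for l in range(n_leaves_per_branch):
            leaf = f"T{b + 1:03d}.{l + 1}"
            parents.append({"term": leaf, "parent": branch})
            members = rng.choice(len(genes), size=min(leaf_size, len(genes)), replace=False)
            for g in members:
                annotations.append({"term": leaf, "gene": genes[g]})
    return pd.DataFrame(parents), pd.DataFrame(annotations)


# ---------------------------------------------------------------------------
# Multi-study collections across two species
# ---------------------------------------------------------------------------


@dataclass
class StudyCollection:
    studies: dict[str, ExpressionStudy]  # profile id -> study
    species_of: dict[str, str]  # profile id -> species tag
    ortholog_map: pd.DataFrame  # columns gene_a, gene_b (1:1)
    truth: pd.DataFrame  # pair, class in {core, discordant, null}, sign


def simulate_study_collection(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> StudyCollection:
    """Two-species panel of two-group aging profiles with planted structure.

    A ``shared_core_fraction`` of ortholog pairs carries same-sign planted
    effects in every profile of both species; a ``discordant_fraction``
    carries opposite signs across species; the rest are null. Species A is
    human-like (young 25 y / old 65 y), species B mouse-like (5 mo / 30 mo);
    planted log2 group differences are equal across species.
    """
    rng = _rng(config, rng)
    if config.n_profiles < 2:
        raise ValueError("need at least 2 profiles per species")
    n = config.n_genes
    genes_a = _gene_ids(n, "h_g")
    genes_b = _gene_ids(n, "m_g")
    n_core = int(round(config.shared_core_fraction * n))
    n_disc = int(round(config.discordant_fraction * n))
    classes = np.array(["core"] * n_core + ["discordant"] * n_disc + ["null"] * (n - n_core - n_disc))
    rng.shuffle(classes)
    sign = rng.choice([-1.0, 1.0], size=n)
    # planted log2 group difference (old - young); sized well above the noise
    delta = np.abs(rng.normal(0.8, 0.2, size=n))
    delta_a = np.where(classes == "null", 0.0, sign * delta)
    delta_b = np.where(classes == "core", delta_a, np.where(classes == "discordant", -delta_a, 0.0))

    species_ages = {"A": (25.0, 65.0, "years"), "B": (5.0, 30.0, "months")}
    studies: dict[str, ExpressionStudy] = {}
    species_of: dict[str, str] = {}
    for species, (young_age, old_age, unit) in species_ages.items():
        delta_s = delta_a if species == "A" else delta_b
        genes = genes_a if species == "A" else genes_b
        for prof in range(config.n_profiles):
            m = 2 * config.n_per_group
            samples = [f"s{i + 1:03d}" for i in range(m)]
            group = np.r_[["young"] * config.n_per_group, ["old"] * config.n_per_group]
            ages = np.r_[np.full(config.n_per_group, young_age), np.full(config.n_per_group, old_age)]
            baseline = rng.uniform(*config.baseline_range, size=n)
            old = group == "old"
            Y = baseline[:, None] + delta_s[:, None] * old[None, :] + rng.normal(0.0, config.noise_sd, (n, m))
            pid = f"{species}{prof + 1}"
            studies[pid] = ExpressionStudy(
                values=pd.DataFrame(Y, index=genes, columns=samples),
                ages=pd.Series(ages, index=samples),
                sex=pd.Series(np.array(["F", "M"] * ((m + 1) // 2))[:m], index=samples),
                species_tag=species,
                design="two_group",
                group=pd.Series(group, index=samples),
                age_unit=unit,
            )
            species_of[pid] = species
    ortholog_map = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    truth = pd.DataFrame(
        {"gene_a": genes_a, "gene_b": genes_b, "truth_class": classes, "truth_sign": np.where(classes == "null", 0, sign).astype(int)}
    )
    return StudyCollection(studies=studies, species_of=species_of, ortholog_map=ortholog_map, truth=truth)
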