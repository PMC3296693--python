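"""Readers and writers for the external formats used across the pipeline.

Expression matrices and all result tables are UTF-8 tab-separated with header
rows; promoter/region sequences travel as FASTA plus a companion region table;
binding-site models are JASPAR-style text matrices. Gene and sample
identifiers are opaque strings throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "ExpressionStudy",
    "PWMRecord",
    "Region",
    "ManifestSummary",
    "read_expression_study",
    "write_expression_study",
    "read_pwm_collection",
    "write_pwm_collection",
    "read_regions",
    "write_regions",
    "summarize_manifest",
]

_VALID_DESIGNS = ("continuous_age", "two_group")
_VALID_AGE_UNITS = ("years", "months")
_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass
class ExpressionStudy:
    """A log2-scale expression matrix (genes x samples) with sample metadata.

    ``ages`` are in study units: years for human-like cohorts sampled over a
    continuous age span, months for mouse-like two-group (young/old) designs.
    """

    values: pd.DataFrame  # genes x samples, log2 scale
    ages: pd.Series  # per sample, strictly positive
    sex: pd.Series  # per sample, "F" or "M"
    species_tag: str = "human"
    design: str = "continuous_age"
    group: pd.Series | None = None  # per sample, "young"/"old" when two_group
    age_unit: str = "years"

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.design not in _VALID_DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.age_unit not in _VALID_AGE_UNITS:
            raise ValueError(f"unknown age unit {self.age_unit!r}")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        for name, series in (("ages", self.ages), ("sex", self.sex)):
            if not series.index.equals(self.values.columns):
                raise ValueError(f"{name} index does not match sample ids")
        if (self.ages <= 0).any():
            bad = self.ages.index[self.ages <= 0][0]
            raise ValueError(f"non-positive age for sample {bad!r}")
        if not set(self.sex.unique()) <= {"F", "M"}:
            raise ValueError("sex labels must be 'F' or 'M'")
        if self.design == "two_group":
            if self.group is None:
                raise ValueError("two_group design requires group labels")
            if not self.group.index.equals(self.values.columns):
                raise ValueError("group index does not match sample ids")
            counts = self.group.value_counts()
            if counts.get("young", 0) == 0 or counts.get("old", 0) == 0:
                raise ValueError("two_group design needs both groups non-empty")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        ids = list(sample_ids)
        return ExpressionStudy(
            values=self.values[ids],
            ages=self.ages[ids],
            sex=self.sex[ids],
            species_tag=self.species_tag,
            design=self.design,
            group=None if self.group is None else self.group[ids],
            age_unit=self.age_unit,
        )


def read_expression_study(
    matrix_path: str | Path,
    metadata_path: str | Path,
    species_tag: str | None = None,
    design: str | None = None,
    age_unit: str | None = None,
) -> ExpressionStudy:
    """Read a genes x samples log2 matrix and its per-sample metadata table.

    The matrix is TSV with a header row of sample ids and a first column of
    gene ids. Metadata is TSV keyed by ``sample`` with ``age`` and ``sex``
    columns and optional ``group``, ``species``, ``design``, ``age_unit``
    columns. Missing or non-numeric cells are rejected, naming the offending
    gene and sample; metadata samples absent from the matrix are rejected.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in meta.columns:
        raise ValueError("metadata must have a 'sample' column")
    meta = meta.set_index("sample")
    missing = [s for s in meta.index if s not in matrix.columns]
    if missing:
        raise ValueError(f"metadata sample {missing[0]!r} absent from matrix")
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"matrix sample {missing[0]!r} absent from metadata")
    # align metadata to matrix column order
    meta = meta.loc[list(matrix.columns)]

    numeric = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for col in matrix.columns:
        converted = pd.to_numeric(matrix[col], errors="coerce")
        if converted.isna().any():
            gene = converted.index[converted.isna()][0]
            raise ValueError(f"missing or non-numeric value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted

    ages = pd.to_numeric(meta["age"], errors="coerce")
    if ages.isna().any():
        raise ValueError(f"non-numeric age for sample {ages.index[ages.isna()][0]!r}")

    group = None
    if "group" in meta.columns and (meta["group"] != "").any():
        group = meta["group"]
    if design is None:
        if "design" in meta.columns and (meta["design"] != "").any():
            design = meta["design"].iloc[0]
        else:
            design = "two_group" if group is not None else "continuous_age"
    if species_tag is None:
        species_tag = meta["species"].iloc[0] if "species" in meta.columns else "unknown"
    if age_unit is None:
        if "age_unit" in meta.columns and (meta["age_unit"] != "").any():
            age_unit = meta["age_unit"].iloc[0]
        else:
            age_unit = "years"
    return ExpressionStudy(
        values=numeric,
        ages=ages,
        sex=meta["sex"],
        species_tag=species_tag,
        design=design,
        group=group,
        age_unit=age_unit,
    )


def write_expression_study(study: ExpressionStudy, matrix_path: str | Path, metadata_path: str | Path) -> None:
    study.values.to_csv(matrix_path, sep="\t", index_label="gene")
    meta = pd.DataFrame(
        {
            "sample": study.sample_ids,
            "age": study.ages.values,
            "sex": study.sex.values,
            "species": study.species_tag,
            "design": study.design,
            "age_unit": study.age_unit,
        }
    )
    if study.group is not None:
        meta["group"] = study.group.values
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

PROB_FLOOR = 1e-4


@dataclass
class PWMRecord:
    """A binding-site model scored as summed log2 posterior/prior ratios.

    ``score_matrix[i, j]`` is log2(p_ij / background_j); a scan window is a
    hit when its summed score exceeds ``threshold`` = 0.9 x ``max_score``
    (the sum of per-position score maxima).
    """

    motif_id: str
    probs: np.ndarray  # L x 4, columns A/C/G/T, rows sum to 1
    background: np.ndarray  # length 4, sums to 1
    score_matrix: np.ndarray = field(init=False)
    max_score: float = field(init=False)
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] == 0:
            raise ValueError(f"motif {self.motif_id}: probability table must be L x 4 with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: probability rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: background must sum to 1")
        self.score_matrix = np.log2(self.probs / self.background)
        self.max_score = float(self.score_matrix.max(axis=1).sum())
        self.threshold = 0.9 * self.max_score

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, background: np.ndarray | None = None
    ) -> "PWMRecord":
        """Build from a count or probability matrix, flooring zero cells.

        Zero probabilities are floored at 1e-4 and rows renormalized so the
        log-odds scores stay finite.
        """
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"motif {motif_id}: empty count row")
        probs = counts / sums
        probs = np.maximum(probs, PROB_FLOOR)
        probs = probs / probs.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id=motif_id, probs=probs, background=background)


def read_pwm_collection(path: str | Path, background: np.ndarray | None = None) -> list[PWMRecord]:
    """Read JASPAR-style count matrices into scored :class:`PWMRecord` objects."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    records = []
    for motif in parsed:
        counts = np.column_stack([motif.counts[b] for b in "ACGT"]).astype(float)
        motif_id = motif.matrix_id or motif.name
        records.append(PWMRecord.from_counts(motif_id, counts, background))
    if not records:
        raise ValueError(f"no motifs found in {path}")
    return records


def write_pwm_collection(records: Sequence[PWMRecord], path: str | Path, scale: float = 1000.0) -> None:
    """Write records as JASPAR-style integer count matrices."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.motif_id} {rec.motif_id}\n")
            counts = np.rint(rec.probs * scale).astype(int)
            for j, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[:, j])
                handle.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Genomic regions
# ---------------------------------------------------------------------------

_VALID_KINDS = ("tss_window", "intergenic", "intron", "conserved_upstream")


@dataclass
class Region:
    """A sequence region, optionally linked to a gene (e.g. its TSS window)."""

    region_id: str
    sequence: str
    kind: str = "tss_window"
    linked_gene: str | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"region {self.region_id}: unknown kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.region_id}: strand must be '+' or '-'")
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"region {self.region_id}: illegal character {sorted(bad)[0]!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_regions(fasta_path: str | Path, table_path: str | Path) -> list[Region]:
    """Read region sequences (FASTA) with their companion annotation table."""
    table = pd.read_csv(table_path, sep="\t", dtype=str, keep_default_na=False)
    table = table.set_index("region_id")
    regions = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in table.index:
            raise ValueError(f"FASTA id {record.id!r} missing from region table")
        row = table.loc[record.id]
        regions.append(
            Region(
                region_id=record.id,
                sequence=str(record.seq),
                kind=row["kind"],
                linked_gene=row["linked_gene"] or None,
                strand=row["strand"],
            )
        )
    return regions


def write_regions(regions: Sequence[Region], fasta_path: str | Path, table_path: str | Path) -> None:
    with open(fasta_path, "w") as handle:
        for region in regions:
            handle.write(f">{region.region_id}\n{region.sequence}\n")
    pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "kind": [r.kind for r in regions],
            "linked_gene": [r.linked_gene or "" for r in regions],
            "strand": [r.strand for r in regions],
        }
    ).to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Compendium manifests
# ---------------------------------------------------------------------------


@dataclass
class ManifestSummary:
    n_arrays: int
    n_treatments: int
    mean_replicates: float


def summarize_manifest(sample_table: pd.DataFrame, treatment_col: str = "treatment") -> ManifestSummary:
    """Summarize a compendium manifest: arrays, treatments, mean replicates.

    ``mean_replicates`` is rounded to two decimals for reporting.
    """
    if len(sample_table) == 0:
        raise ValueError("empty manifest")
    n_arrays = len(sample_table)
    n_treatments = sample_table[treatment_col].nunique()
    return ManifestSummary(
        n_arrays=n_arrays,
        n_treatments=n_treatments,
        mean_replicates=round(n_arrays / n_treatments, 2),
    )
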