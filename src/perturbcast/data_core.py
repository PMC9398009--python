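"""Domain containers and tabular I/O for expression, perturbation and
dose-response data, plus preprocessing and replicate-quality partitioning.

Expression matrices are genes x samples. Perturbation records carry the
drug-induced differential expression (dgx) of a configurable gene panel
(978 landmark genes at full scale; smaller panels for desk-scale runs).
Replicate sets of the same (drug, cell, dose, time) condition are kept or
discarded by their average inter-replicate Pearson correlation: profiles
whose replicates agree poorly are unreliable labels and are routed to the
low-quality pool used only for pseudo-label augmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GENE_PANEL_SIZE = 978
QUALITY_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a raw/log2 space tag."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    space_tag: str = "raw"  # {"raw", "log2"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def profile(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PerturbationRecord:
    """One (drug, cell, dose, time) sample with its dgx label vector."""

    drug_id: str
    smiles: str
    cell_id: str
    dose: float  # uM
    time_h: float
    dgx: np.ndarray

    def __post_init__(self):
        self.dgx = np.asarray(self.dgx, dtype=float)
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")

    @property
    def key(self) -> tuple:
        return (self.drug_id, self.cell_id, self.dose, self.time_h)


@dataclass
class ReplicateSet:
    """All biological replicates of one (drug, cell, dose, time) condition."""

    key: tuple
    replicates: list[np.ndarray]
    smiles: str = ""

    def __post_init__(self):
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        if not self.replicates:
            raise ValueError("a ReplicateSet needs at least one replicate")
        lengths = {len(r) for r in self.replicates}
        if len(lengths) != 1:
            raise ValueError(f"replicate vectors have unequal lengths: {sorted(lengths)}")

    def consensus(self) -> np.ndarray:
        """Elementwise mean over replicates, the training label for the set."""
        return np.mean(self.replicates, axis=0)

    def to_record(self) -> PerturbationRecord:
        drug_id, cell_id, dose, time_h = self.key
        return PerturbationRecord(drug_id, self.smiles, cell_id, dose, time_h, self.consensus())


@dataclass
class DoseResponsePoint:
    """One viability measurement, as a fraction of untreated control."""

    drug_id: str
    cell_id: str
    dose: float  # uM
    viability: float

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if not math.isfinite(self.viability):
            raise ValueError("viability must be finite")


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def load_expression_matrix(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples table (header = sample ids, first column = gene id).

    ``fmt`` is one of ``tsv``, ``csv`` or ``gct`` (v1.2: two header lines,
    then NAME/Description columns before the samples).
    """
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"ragged/malformed table in {path}: {exc}") from exc
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line: {version!r}")
            fh.readline()  # dims line; shape is validated against the body
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected tsv, csv or gct")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene ids: {dupes}")
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(m: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    if fmt in ("tsv", "csv"):
        m.to_dataframe().to_csv(path, sep="\t" if fmt == "tsv" else ",",
                                index_label="gene_id", float_format="%.17g")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            df = m.to_dataframe()
            df.insert(0, "Description", "na")
            df.to_csv(fh, sep="\t", index_label="NAME", float_format="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Perturbation / dose-response table I/O
# ---------------------------------------------------------------------------

_PERT_META_COLS = ["drug_id", "smiles", "cell_id", "dose_uM", "time_h"]


def load_perturbation_table(path) -> list[PerturbationRecord]:
    """TSV with columns drug_id, smiles, cell_id, dose_uM, time_h, then the
    dgx columns (one per panel gene, in panel order)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PERT_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"perturbation table missing columns: {missing}")
    dgx_cols = [c for c in df.columns if c not in _PERT_META_COLS]
    if not dgx_cols:
        raise ValueError("perturbation table has no dgx columns")
    return [
        PerturbationRecord(
            drug_id=str(row.drug_id), smiles=str(row.smiles), cell_id=str(row.cell_id),
            dose=float(row.dose_uM), time_h=float(row.time_h),
            dgx=row[dgx_cols].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]


def write_perturbation_table(records: list[PerturbationRecord], path,
                             gene_ids: list[str] | None = None) -> None:
    if not records:
        raise ValueError("no records to write")
    g = len(records[0].dgx)
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    rows = []
    for r in records:
        row = {"drug_id": r.drug_id, "smiles": r.smiles, "cell_id": r.cell_id,
               "dose_uM": r.dose, "time_h": r.time_h}
        row.update(dict(zip(gene_ids, r.dgx)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_dose_response_table(path, unit: str = "fraction") -> list[DoseResponsePoint]:
    """TSV with columns drug_id, cell_id, dose_uM, viability.

    ``unit='percent'`` divides viability by 100 at load.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["drug_id", "cell_id", "dose_uM", "viability"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    scale = 0.01 if unit == "percent" else 1.0
    return [
        DoseResponsePoint(str(r.drug_id), str(r.cell_id), float(r.dose_uM),
                          float(r.viability) * scale)
        for _, r in df.iterrows()
    ]


def write_dose_response_table(points: list[DoseResponsePoint], path) -> None:
    pd.DataFrame(
        [{"drug_id": p.drug_id, "cell_id": p.cell_id, "dose_uM": p.dose,
          "viability": p.viability} for p in points]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, pseudocount: float = 0.001) -> ExpressionMatrix:
    """log2(x + pseudocount) on a raw-space matrix (raises if already log2)."""
    if m.space_tag != "raw":
        raise ValueError(f"log2_transform requires raw-space input, got {m.space_tag!r}")
    neg = np.argwhere(m.values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative expression value at gene {m.gene_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids), sample_ids=list(m.sample_ids),
        values=np.log2(m.values + pseudocount), space_tag="log2",
    )


# ---------------------------------------------------------------------------
# Replicate quality
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    # centered-sum formulation: exact for integer-valued fixtures whose
    # cross/auto sums are perfect squares
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("zero-variance replicate vector in correlation")
    return float(xc @ yc) / denom


def average_replicate_correlation(rs: ReplicateSet) -> float:
    """Mean Pearson correlation over all unordered replicate pairs."""
    reps = rs.replicates
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates for a correlation")
    pairs = [
        _pearson(reps[i], reps[j])
        for i in range(len(reps))
        for j in range(i + 1, len(reps))
    ]
    return float(np.mean(pairs))


def partition_by_quality(
    sets: list[ReplicateSet], threshold: float = QUALITY_THRESHOLD
) -> tuple[list[ReplicateSet], list[ReplicateSet]]:
    """Split replicate sets at average correlation strictly > ``threshold``.

    Single-replicate sets cannot attest their own quality and go to the
    low pool. Returns (high, low); high sets provide consensus training
    labels, low sets feed the teacher-student augmentation loop.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    high: list[ReplicateSet] = []
    low: list[ReplicateSet] = []
    for rs in sets:
        if len(rs.replicates) < 2:
            low.append(rs)
        elif average_replicate_correlation(rs) > threshold:
            high.append(rs)
        else:
            low.append(rs)
    return high, low


def group_replicates(records: list[PerturbationRecord]) -> list[ReplicateSet]:
    """Group perturbation records into replicate sets by (drug, cell, dose, time)."""
    groups: dict[tuple, ReplicateSet] = {}
    for r in records:
        if r.key in groups:
            groups[r.key].replicates.append(r.dgx)
        else:
            groups[r.key] = ReplicateSet(key=r.key, replicates=[r.dgx], smiles=r.smiles)
    return list(groups.values())
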