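"""Readers/writers for genotype, phenotype and result files, and the
per-training-set segregation filter.

Two genotype dialects are supported:

* ``tsv`` — header ``animal_id line generation marker...``, one row per
  animal, dosages as 0/1/2 integers.
* ``plink_raw`` — a PLINK-.raw-style dialect: columns ``FID IID PAT MAT SEX
  PHENOTYPE`` followed by one integer dosage column per marker. PAT/MAT/SEX
  are written as 0 and ignored on read. FID carries ``line/generation`` so
  the round-trip is the identity.

Missing genotypes are an error in both dialects: the source data this
emulates was fully edited upstream, and an explicit failure beats silent
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import GenotypePanel

__all__ = [
    "MarkerFilterReport",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_nonsegregating",
    "write_results",
]

_DIALECTS = ("tsv", "plink_raw")


@dataclass
class MarkerFilterReport:
    n_markers_in: int
    n_segregating: int
    removed_marker_ids: list

    def __post_init__(self) -> None:
        if self.n_segregating > self.n_markers_in:
            raise ValueError("segregating count exceeds input count")


def _check_dosages(values: pd.DataFrame, animal_ids: np.ndarray) -> np.ndarray:
    arr = values.to_numpy()
    if arr.dtype == object or np.issubdtype(arr.dtype, np.floating):
        flat = pd.to_numeric(values.stack(), errors="coerce")
        bad = flat[~flat.isin((0.0, 1.0, 2.0))]
        if len(bad) or flat.isna().any():
            row, marker = (
                bad.index[0] if len(bad) else flat[flat.isna()].index[0]
            )
            raise ValueError(
                f"invalid genotype for animal {animal_ids[row]!r} at marker "
                f"{marker!r}: dosages must be integers in {{0,1,2}} with no "
                "missing values"
            )
        arr = flat.unstack().to_numpy()
    arr = arr.astype(np.int64)
    if arr.size and not np.isin(arr, (0, 1, 2)).all():
        row, col = np.argwhere(~np.isin(arr, (0, 1, 2)))[0]
        raise ValueError(
            f"invalid genotype for animal {animal_ids[row]!r} at marker "
            f"{values.columns[col]!r}: dosage {arr[row, col]} out of range"
        )
    return arr.astype(np.int8)


def write_genotypes(panel: GenotypePanel, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        df = pd.DataFrame(panel.genotypes, columns=panel.markers)
        df.insert(0, "generation", panel.generation)
        df.insert(0, "line", panel.line_labels)
        df.insert(0, "animal_id", panel.animal_ids)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "plink_raw":
        df = pd.DataFrame(panel.genotypes, columns=panel.markers)
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", panel.animal_ids)
        fid = np.char.add(np.char.add(panel.line_labels, "/"), panel.generation)
        df.insert(0, "FID", fid)
        df.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(path, dialect: str = "tsv") -> GenotypePanel:
    """Read a genotype panel; round-trips :func:`write_genotypes` exactly."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else r"\s+"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if dialect == "tsv":
        expected = ("animal_id", "line", "generation")
        if tuple(df.columns[:3]) != expected:
            raise ValueError(f"tsv genotype header must start with {expected}")
        meta, markers = df.iloc[:, :3], df.columns[3:]
        animal_ids = meta["animal_id"].to_numpy(dtype=str)
        lines = meta["line"].to_numpy(dtype=str)
        gens = meta["generation"].to_numpy(dtype=str)
    else:
        expected = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
        if tuple(df.columns[:6]) != expected:
            raise ValueError(f"plink_raw header must start with {expected}")
        markers = df.columns[6:]
        animal_ids = df["IID"].to_numpy(dtype=str)
        fid = df["FID"].to_numpy(dtype=str)
        split = np.char.partition(fid, "/")
        lines = split[:, 0]
        gens = np.where(split[:, 2] == "", "train", split[:, 2])
    geno = _check_dosages(df[markers], animal_ids)
    return GenotypePanel(animal_ids, lines, gens, markers.to_numpy(dtype=str), geno)


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    cols = ["animal_id", "line", "generation", "hatch_week", "phenotype", "tbv"]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype frame lacks columns {missing}")
    frame[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError("phenotype file must carry animal_id and phenotype")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def join_phenotypes(panel: GenotypePanel, phen: pd.DataFrame) -> pd.DataFrame:
    """Align a phenotype table with a panel by animal_id, error on mismatch."""
    indexed = phen.set_index("animal_id")
    missing = [a for a in panel.animal_ids if a not in indexed.index]
    if missing:
        raise ValueError(f"phenotypes missing for animals {missing[:5]}...")
    return indexed.loc[panel.animal_ids].reset_index()


def filter_nonsegregating(
    panel: GenotypePanel, training_ids
) -> tuple[GenotypePanel, MarkerFilterReport]:
    """Drop markers with zero genotype variance among the training animals.

    The filter is defined by the training set only and applied to every
    animal in the panel, mirroring per-training-set SNP editing. Idempotent.
    """
    training_ids = np.asarray(list(training_ids), dtype=str)
    if len(training_ids) == 0:
        raise ValueError("training set is empty")
    id_set = set(panel.animal_ids.tolist())
    stray = [a for a in training_ids if a not in id_set]
    if stray:
        raise ValueError(f"training ids not in panel: {stray[:5]}")
    mask = np.isin(panel.animal_ids, training_ids)
    train_geno = panel.genotypes[mask]
    segregating = train_geno.min(axis=0) != train_geno.max(axis=0)
    report = MarkerFilterReport(
        n_markers_in=panel.n_markers,
        n_segregating=int(segregating.sum()),
        removed_marker_ids=panel.markers[~segregating].tolist(),
    )
    return panel.subset_markers(segregating), report


def write_results(df: pd.DataFrame, path) -> None:
    """Write tidy results: validation_line, training_set, model, metric, value."""
    cols = ["validation_line", "training_set", "model", "metric", "value"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"result frame lacks columns {missing}")
    df[cols].to_csv(path, index=False)
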