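"""Readers and writers for the pipeline's tabular formats.

Formats handled: intensity TSV (MaxQuant proteinGroups-style subset: one id
column plus one non-negative intensity column per sample), paired design CSV
(subject, sample, condition), GMT gene-set files, and generic result TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "PairedDesign",
    "GeneSetCollection",
    "read_intensity_table",
    "read_design",
    "read_gene_sets",
    "write_gene_sets",
    "write_intensity_table",
    "write_design",
    "write_results_table",
]

DEFAULT_ID_COLUMN = "Protein IDs"


@dataclass
class IntensityMatrix:
    """Protein x sample matrix of non-negative label-free intensities.

    A value of 0 means "not observed"; NaN and blank cells are normalized
    to 0 on load.  Semicolon-joined accession groups are kept verbatim as a
    single protein id.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_proteins, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("protein_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        np.nan_to_num(self.values, copy=False, nan=0.0)
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative intensity for protein {self.protein_ids[i]!r} "
                f"in sample {self.sample_ids[j]!r}"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not found in matrix") from None

    def to_frame(self, id_column: str = DEFAULT_ID_COLUMN) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, id_column, self.protein_ids)
        return df


@dataclass
class PairedDesign:
    """Subject -> (sample in condition A, sample in condition B) pairing."""

    subjects: list[str]
    condition_a: str
    condition_b: str
    # subject -> {condition: sample_id}
    pairs: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("paired design requires at least 2 subjects")
        seen: set[str] = set()
        for subj in self.subjects:
            conds = self.pairs.get(subj, {})
            for cond in (self.condition_a, self.condition_b):
                if cond not in conds:
                    raise ValueError(f"subject {subj!r} has no sample in condition {cond!r}")
                sample = conds[cond]
                if sample in seen:
                    raise ValueError(f"sample {sample!r} appears in more than one pair")
                seen.add(sample)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.condition_a, self.condition_b)

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids for one condition, in subject order."""
        if condition not in (self.condition_a, self.condition_b):
            raise KeyError(f"unknown condition {condition!r}")
        return [self.pairs[s][condition] for s in self.subjects]

    def all_samples(self) -> list[str]:
        out = []
        for subj in self.subjects:
            out.append(self.pairs[subj][self.condition_a])
            out.append(self.pairs[subj][self.condition_b])
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets: term id -> (description, member accession list)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_intensity_table(
    path: str | Path,
    id_column: str = DEFAULT_ID_COLUMN,
    drop_ids: Sequence[str] | None = None,
) -> IntensityMatrix:
    """Read a protein x sample intensity TSV.

    Parameters
    ----------
    path
        Tab-separated file, first row header, containing `id_column` plus
        one numeric column per sample.
    id_column
        Name of the protein accession column.
    drop_ids
        Optional accessions to discard after loading (e.g. contaminant or
        reverse hits); defaults to no filtering.

    Raises
    ------
    ValueError
        On duplicate protein ids or negative intensities (with location).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    sample_cols = [c for c in df.columns if c != id_column]
    if not sample_cols:
        raise ValueError(f"no sample columns found in {path}")
    protein_ids = df[id_column].astype(str).tolist()
    dupes = pd.Series(protein_ids)[pd.Series(protein_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate protein id {dupes.iloc[0]!r} in {path}")
    values = df[sample_cols].to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative intensity at row {i + 2} (protein {protein_ids[i]!r}), "
            f"column {sample_cols[j]!r} in {path}"
        )
    m = IntensityMatrix(protein_ids=protein_ids, sample_ids=sample_cols, values=values)
    if drop_ids:
        keep = [i for i, p in enumerate(m.protein_ids) if p not in set(drop_ids)]
        m = IntensityMatrix(
            protein_ids=[m.protein_ids[i] for i in keep],
            sample_ids=m.sample_ids,
            values=m.values[keep],
        )
    return m


def write_intensity_table(
    m: IntensityMatrix, path: str | Path, id_column: str = DEFAULT_ID_COLUMN
) -> None:
    m.to_frame(id_column).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_design(path: str | Path) -> PairedDesign:
    """Read a paired design CSV with columns subject, sample, condition.

    Exactly two condition labels must be present and every subject must
    contribute exactly one sample per condition.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"design file {path} is empty") from None
    required = {"subject", "sample", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file {path} must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"design file {path} has no rows")
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(
            f"design file {path} has {len(conditions)} condition labels "
            f"({conditions}); exactly 2 required"
        )
    cond_a, cond_b = conditions
    pairs: dict[str, dict[str, str]] = {}
    subjects: list[str] = []
    for _, row in df.iterrows():
        subj, sample, cond = row["subject"], row["sample"], row["condition"]
        if subj not in pairs:
            pairs[subj] = {}
            subjects.append(subj)
        if cond in pairs[subj]:
            raise ValueError(
                f"subject {subj!r} has more than one sample in condition {cond!r}"
            )
        pairs[subj][cond] = sample
    return PairedDesign(subjects=subjects, condition_a=cond_a, condition_b=cond_b, pairs=pairs)


def write_design(d: PairedDesign, path: str | Path) -> None:
    rows = []
    for subj in d.subjects:
        for cond in d.conditions:
            rows.append({"subject": subj, "sample": d.pairs[subj][cond], "condition": cond})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> member [<tab> member ...].

    Duplicate members within a line are stored once (first occurrence order).
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {term!r} has no members")
            sets[term] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(g: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in g.sets.items():
            fh.write("\t".join([term, desc, *members]) + "\n")


def write_results_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as a TSV with header.

    Floats are serialized with 12 significant digits; row order is preserved
    as given.  `columns` fixes the header (useful for an empty record list,
    which then yields a header-only file).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=list(columns) if columns is not None else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
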