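"""Reading, validation and assembly of cell-sorted methylation data.

The pipeline consumes plain tabular text: a probe × sample matrix of
β-values (first column ``probe_id``, header row of sample ids), a sample
sheet mapping each sample to a subject, a cell type and a sex, and
optionally a probe annotation table (chromosome, position, gene, genomic
feature, SNP flag).  Assembly turns these into a per-sex K × n × J tensor
of β-values indexed by CpG probe × subject × cell type; subjects missing
any cell type and probes missing any value are dropped with a logged
count — the model has no missing-data mechanism.

All tool outputs are tab-delimited text with a ``#``-prefixed metadata
header block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("methylselect")

__all__ = [
    "SampleSheet",
    "MethylationDataset",
    "FEATURE_VOCABULARY",
    "load_beta_matrix",
    "read_sample_sheet",
    "read_annotation",
    "assemble_dataset",
    "cross_tabulate_features",
    "write_tsv",
    "read_tsv",
]

FEATURE_VOCABULARY = (
    "1stExon", "3'UTR", "5'UTR", "Body", "Intergenic", "TSS1500", "TSS200",
)

SEXES = ("F", "M")


def _read_table(path, delimiter=None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=delimiter, comment="#")


def load_beta_matrix(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probe × sample β-value matrix from delimited text.

    The first column holds probe ids (made the index), the header row
    sample ids, and the body numeric β-values.  Duplicate probe ids and
    values outside [0,1] are hard errors naming the offenders; missing
    cells are tolerated here and resolved at assembly.
    """
    df = _read_table(path, delimiter)
    probe_col = df.columns[0]
    probes = df[probe_col].astype(str)
    dup = probes[probes.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate probe_id(s) in {path}: {', '.join(dup[:5])}")
    body = df.drop(columns=[probe_col])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad_parse = body.notna() & numeric.isna()
    if bad_parse.to_numpy().any():
        cells = _offending_cells(bad_parse, probes)
        raise ValueError(f"non-numeric β-values in {path}: {cells}")
    out_of_range = (numeric < 0) | (numeric > 1)
    if out_of_range.to_numpy().any():
        cells = _offending_cells(out_of_range.fillna(False), probes)
        raise ValueError(f"β-values outside [0,1] in {path}: {cells}")
    numeric.index = pd.Index(probes, name="probe_id")
    return numeric


def _offending_cells(mask: pd.DataFrame, probes: pd.Series, limit: int = 5) -> str:
    rows, cols = np.nonzero(mask.to_numpy())
    cells = [f"({probes.iloc[r]}, {mask.columns[c]})" for r, c in zip(rows[:limit], cols[:limit])]
    extra = "" if len(rows) <= limit else f" and {len(rows) - limit} more"
    return ", ".join(cells) + extra


@dataclass
class SampleSheet:
    """Mapping of array samples to subject, cell type and sex."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "cell_type", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {', '.join(missing)}")
        t = self.table = self.table.astype(
            {c: str for c in self.REQUIRED}
        ).reset_index(drop=True)
        dup = t["sample_id"][t["sample_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample_id(s): {', '.join(dup[:5])}")
        bad_sex = sorted(set(t["sex"]) - set(SEXES))
        if bad_sex:
            raise ValueError(f"sex must be one of {SEXES}; got {bad_sex}")
        key = t[["subject_id", "cell_type", "sex"]]
        if key.duplicated().any():
            rows = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (subject_id, cell_type, sex) combination: "
                f"({rows.subject_id}, {rows.cell_type}, {rows.sex})"
            )
        for sex in sorted(set(t["sex"])):
            if t.loc[t["sex"] == sex, "cell_type"].nunique() < 2:
                raise ValueError(f"fewer than 2 distinct cell types for sex {sex}")

    def for_sex(self, sex: str) -> pd.DataFrame:
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        return self.table[self.table["sex"] == sex]


def read_sample_sheet(path, delimiter: str | None = None) -> SampleSheet:
    return SampleSheet(_read_table(path, delimiter))


def read_annotation(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table; probe_id becomes the unique index.

    Required columns: probe_id, chromosome, position, feature; optional:
    gene, snp_on_cpg.  Features must come from the fixed vocabulary.
    """
    df = _read_table(path, delimiter)
    required = ("probe_id", "chromosome", "position", "feature")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing column(s): {', '.join(missing)}")
    df["probe_id"] = df["probe_id"].astype(str)
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].unique()
        raise ValueError(f"duplicate probe_id(s) in annotation: {', '.join(dup[:5])}")
    bad = sorted(set(df["feature"]) - set(FEATURE_VOCABULARY))
    if bad:
        raise ValueError(
            f"unknown genomic feature(s) {bad}; expected {FEATURE_VOCABULARY}"
        )
    if "gene" not in df.columns:
        df["gene"] = ""
    if "snp_on_cpg" not in df.columns:
        df["snp_on_cpg"] = False
    df["snp_on_cpg"] = df["snp_on_cpg"].astype(bool)
    df["position"] = df["position"].astype(int)
    return df.set_index("probe_id")


@dataclass
class MethylationDataset:
    """β-values of one sex as a K × n × J tensor (probe × subject × cell
    type), complete (no missing entries) by construction."""

    probe_ids: list[str]
    cell_types: tuple[str, ...]
    subjects: list[str]
    beta: np.ndarray
    sex: str | None = None
    n_probes_dropped: int = 0
    n_subjects_dropped: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        K, n, J = self.beta.shape
        if (K, n, J) != (len(self.probe_ids), len(self.subjects), len(self.cell_types)):
            raise ValueError("beta shape does not match index lengths")
        if J < 2:
            raise ValueError("at least 2 cell types are required")
        if n < 2:
            raise ValueError("at least 2 subjects are required")
        if np.isnan(self.beta).any():
            raise ValueError("assembled dataset must not contain missing values")
        if self.beta.min() < 0 or self.beta.max() > 1:
            raise ValueError("β-values must lie in [0,1]")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.beta.shape[1]

    @property
    def n_cell_types(self) -> int:
        return self.beta.shape[2]

    def to_beta_frame(self) -> pd.DataFrame:
        """Flatten back to a probe × sample matrix with ``subject.celltype``
        sample ids (value-identical round trip)."""
        cols = {}
        for i, subj in enumerate(self.subjects):
            for j, ct in enumerate(self.cell_types):
                cols[f"{subj}.{ct}"] = self.beta[:, i, j]
        return pd.DataFrame(cols, index=pd.Index(self.probe_ids, name="probe_id"))


def assemble_dataset(
    beta_table: pd.DataFrame,
    sheet: SampleSheet,
    sex: str,
    cell_type_order=None,
) -> MethylationDataset:
    """Assemble the per-sex K × n × J tensor from a β-matrix and sheet.

    Cell-type order is lexicographic unless ``cell_type_order`` (e.g. a
    lineage leaf ordering) is supplied.  Subjects lacking any cell type
    and probes with any missing value are dropped with logged counts.
    """
    sub = sheet.for_sex(sex)
    if sub.empty:
        raise ValueError(f"sample sheet contains no samples for sex {sex!r}")
    missing = sorted(set(sub["sample_id"]) - set(map(str, beta_table.columns)))
    if missing:
        raise ValueError(
            f"sample_id(s) absent from the β-matrix: {', '.join(missing[:5])}"
        )
    cell_types = sorted(sub["cell_type"].unique())
    if cell_type_order is not None:
        extra = sorted(set(cell_type_order) - set(cell_types))
        if extra:
            raise ValueError(f"cell type(s) observed for no subject: {', '.join(extra)}")
        cell_types = [ct for ct in cell_type_order if ct in cell_types]
    J = len(cell_types)

    grid = sub.pivot(index="subject_id", columns="cell_type", values="sample_id")
    complete = grid.dropna(axis=0, how="any")
    n_dropped_subj = len(grid) - len(complete)
    if n_dropped_subj:
        dropped = sorted(set(grid.index) - set(complete.index))
        logger.warning(
            "assemble_dataset(sex=%s): dropped %d incomplete subject(s): %s",
            sex, n_dropped_subj, ", ".join(dropped),
        )
    if len(complete) < 2:
        raise ValueError(
            f"fewer than 2 complete subjects for sex {sex!r} "
            f"({len(complete)} after dropping incomplete)"
        )
    subjects = sorted(complete.index)
    K = len(beta_table)
    tensor = np.empty((K, len(subjects), J))
    for i, subj in enumerate(subjects):
        for j, ct in enumerate(cell_types):
            tensor[:, i, j] = beta_table[complete.loc[subj, ct]].to_numpy(dtype=float)

    keep = ~np.isnan(tensor).any(axis=(1, 2))
    n_dropped_probes = int((~keep).sum())
    if n_dropped_probes:
        logger.warning(
            "assemble_dataset(sex=%s): dropped %d probe(s) with missing values",
            sex, n_dropped_probes,
        )
    probe_ids = [str(p) for p, k in zip(beta_table.index, keep) if k]
    return MethylationDataset(
        probe_ids=probe_ids,
        cell_types=tuple(cell_types),
        subjects=subjects,
        beta=tensor[keep],
        sex=sex,
        n_probes_dropped=n_dropped_probes,
        n_subjects_dropped=n_dropped_subj,
    )


def cross_tabulate_features(panel, annotation: pd.DataFrame) -> pd.DataFrame:
    """Distribution of genomic features among the probes of a marker panel.

    Returns a table over the fixed feature vocabulary with counts and
    percentages (summing to 100 over annotated probes).  Probes absent
    from the annotation are counted as unannotated and reported via the
    result's ``attrs['n_unannotated']`` and a warning.
    """
    probes = panel.probe_ids if hasattr(panel, "probe_ids") else list(panel)
    out = pd.DataFrame(
        {"feature": FEATURE_VOCABULARY, "count": 0, "percent": 0.0}
    ).set_index("feature")
    if not probes:
        logger.warning("cross_tabulate_features: empty marker panel")
        out.attrs["n_unannotated"] = 0
        return out.reset_index()
    present = [p for p in probes if p in annotation.index]
    n_unannot = len(probes) - len(present)
    if n_unannot:
        logger.warning(
            "cross_tabulate_features: %d probe(s) missing from annotation", n_unannot
        )
    counts = annotation.loc[present, "feature"].value_counts()
    for feat, cnt in counts.items():
        out.loc[feat, "count"] = int(cnt)
    if len(present):
        out["percent"] = 100.0 * out["count"] / len(present)
    out.attrs["n_unannotated"] = n_unannot
    return out.reset_index()


# ---------------------------------------------------------------------------
# tabular output with metadata header


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with a '#'-prefixed metadata header block."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_tsv`; returns (table, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta
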