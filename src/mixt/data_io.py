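"""On-disk artifacts and their validation.

Containers for the matched two-tissue cohort: gene×sample expression matrices
(log scale) for tumor and blood, a per-patient clinical table with declared
attribute types, and named gene-set collections (GMT).  All tabular formats
are plain TSV so every intermediate is diff-able.

Gene identity is by exact string match; no symbol aliasing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._util import log, read_tsv

TISSUES = ("tumor", "blood")
ROLES = ("patient", "control")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples log-scale expression for one tissue.

    ``values`` is a DataFrame with gene IDs as index and sample IDs as
    columns; ``roles`` maps each sample to ``"patient"`` or ``"control"``.
    Controls are only meaningful in blood (the tissue sampled from both
    cancer patients and cancer-free women).
    """

    values: pd.DataFrame
    tissue: str
    roles: pd.Series

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        vals = self.values
        if vals.index.duplicated().any():
            dup = vals.index[vals.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if vals.columns.duplicated().any():
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan)))
            g, s = vals.index[bad[0, 0]], vals.columns[bad[0, 1]]
            raise ValueError(f"missing/non-finite expression value at gene {g!r}, sample {s!r}")
        self.roles = self.roles.reindex(vals.columns)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()][0]
            raise ValueError(f"no role declared for sample {missing!r}")
        if not self.roles.isin(ROLES).all():
            raise ValueError(f"roles must be in {ROLES}")
        if self.tissue != "blood" and (self.roles == "control").any():
            raise ValueError("controls are only allowed in blood")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def patient_samples(self) -> pd.Index:
        return self.values.columns[self.roles == "patient"]

    @property
    def control_samples(self) -> pd.Index:
        return self.values.columns[self.roles == "control"]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return ExpressionMatrix(self.values[samples], self.tissue, self.roles[samples])

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")


def read_expression(path, tissue: str, roles=None) -> ExpressionMatrix:
    """Read a tab-delimited genes×samples matrix (first column = gene IDs).

    ``roles`` may be a mapping/Series sample→role, a single role string
    applied to every sample, or ``None`` (all samples are patients).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    na = df.isna()
    if na.to_numpy().any():
        bad = np.argwhere(na.to_numpy())
        coords = ", ".join(
            f"(gene {df.index[i]!r}, sample {df.columns[j]!r})" for i, j in bad[:5]
        )
        raise ValueError(f"{path}: missing values at {coords}")
    if roles is None or isinstance(roles, str):
        role_series = pd.Series(roles or "patient", index=df.columns)
    else:
        role_series = pd.Series(roles).reindex(df.columns)
    return ExpressionMatrix(df, tissue, role_series)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """One row per patient; attribute types declared as continuous/categorical.

    Missing values are permitted (NaN) and dropped per-test downstream.
    """

    data: pd.DataFrame  # indexed by patient_id
    types: dict = field(default_factory=dict)  # column -> "continuous" | "categorical"

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate patient_id: {dup!r}")
        for col in self.data.columns:
            if col not in self.types:
                self.types[col] = (
                    "continuous" if pd.api.types.is_numeric_dtype(self.data[col]) else "categorical"
                )
        unknown = set(self.types.values()) - {"continuous", "categorical"}
        if unknown:
            raise ValueError(f"unknown attribute types: {unknown}")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    def attribute(self, name: str) -> pd.Series:
        return self.data[name]

    def to_tsv(self, path, sidecar=None) -> None:
        self.data.rename_axis("patient_id").to_csv(path, sep="\t")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                yaml.safe_dump({"types": self.types}, fh)


def read_clinical(path, types=None, sidecar=None) -> ClinicalTable:
    """Read a clinical table (TSV/CSV, patient_id column) with declared dtypes.

    Type declarations come from ``types`` (dict), a YAML ``sidecar`` with a
    ``types:`` mapping, or are inferred from column dtypes.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a patient_id column")
    df = df.set_index("patient_id")
    df.index = df.index.astype(str)
    if types is None and sidecar is not None:
        with open(sidecar) as fh:
            types = yaml.safe_load(fh)["types"]
    return ClinicalTable(df, dict(types or {}))


# ---------------------------------------------------------------------------
# Matched cohort
# ---------------------------------------------------------------------------

@dataclass
class MatchedCohort:
    """Tumor + blood expression for the same patients, plus clinical data.

    ``matching`` maps patient_id → (tumor sample, blood sample).  The shared
    gene universe is the intersection of the two tissues' gene lists; it is
    used only for cross-tissue gene-overlap tests — each tissue's network is
    built on its own full gene list.
    """

    tumor: ExpressionMatrix
    blood: ExpressionMatrix
    clinical: ClinicalTable
    matching: pd.DataFrame  # index patient_id, columns tumor_sample, blood_sample

    @property
    def patients(self) -> pd.Index:
        return self.matching.index

    @property
    def shared_genes(self) -> pd.Index:
        return self.tumor.gene_ids.intersection(self.blood.gene_ids)

    def expr(self, tissue: str) -> ExpressionMatrix:
        return {"tumor": self.tumor, "blood": self.blood}[tissue]


def build_cohort(tumor: ExpressionMatrix, blood: ExpressionMatrix,
                 clinical: ClinicalTable) -> MatchedCohort:
    """Match patients across tissues on patient_id == sample_id.

    Patient samples present in only one tissue (or missing from the clinical
    table) are dropped with a warning; blood controls are always retained.
    """
    t_pat = set(tumor.patient_samples)
    b_pat = set(blood.patient_samples)
    matched = [p for p in clinical.patient_ids if p in t_pat and p in b_pat]
    dropped = (t_pat | b_pat | set(clinical.patient_ids)) - set(matched)
    if dropped:
        log.warning("dropping %d unmatched patient samples: %s",
                    len(dropped), sorted(dropped)[:10])
    if not matched:
        raise ValueError("zero matched patients between tumor and blood")
    if len(tumor.gene_ids.intersection(blood.gene_ids)) == 0:
        raise ValueError("empty shared gene universe (disjoint gene lists)")
    matching = pd.DataFrame(
        {"tumor_sample": matched, "blood_sample": matched},
        index=pd.Index(matched, name="patient_id"),
    )
    keep_blood = pd.Index(matched).append(blood.control_samples)
    return MatchedCohort(
        tumor=tumor.subset_samples(matched),
        blood=blood.subset_samples(keep_blood),
        clinical=ClinicalTable(clinical.data.loc[matched].copy(), dict(clinical.types)),
        matching=matching,
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict  # name -> tuple of genes
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene...

    Genes are deduplicated within a set (first occurrence kept).
    """
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Module assignments
# ---------------------------------------------------------------------------

def write_modules_tsv(module_set, path) -> None:
    df = pd.DataFrame({
        "gene": module_set.assignment.index,
        "tissue": module_set.tissue,
        "module": module_set.assignment.values,
    })
    df.to_csv(path, sep="\t", index=False)


def read_modules_tsv(path, tissue=None):
    from .network import ModuleSet

    df = read_tsv(path, dtype=str)
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    tissues = df["tissue"].unique()
    if len(tissues) != 1:
        raise ValueError(f"{path}: expected a single tissue, found {list(tissues)}")
    assignment = pd.Series(df["module"].values, index=pd.Index(df["gene"], name="gene"))
    return ModuleSet(tissue=tissues[0], assignment=assignment, params={})
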