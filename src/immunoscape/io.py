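"""Readers, writers and validated domain containers.

Three containers flow through every stage of the pipeline:

* :class:`ExpressionMatrix` — genes × samples of non-negative normalized
  expression (RSEM-like units). The pipeline never re-normalizes; stages
  that need log scale apply ``log2(x + 1)`` themselves.
* :class:`GeneSetCollection` — named gene-ID sets parsed from GMT
  (immune signatures, hallmark pathways, drug-target lists).
* :class:`ClinicalTable` — per-sample survival, staging, demographics,
  mutation status and tumor/normal pairing.

Gene identity is exact string match throughout; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "FormatError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_gene_list",
    "write_results_table",
]


class FormatError(ValueError):
    """A file violated the expected format or a container invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of non-negative, finite expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 1:
            raise FormatError("expression matrix needs at least 1 gene and 1 sample")
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {label} ID: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression for gene {self.gene_ids[g]!r} "
                f"in sample {self.sample_ids[s]!r}"
            )
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression for gene {self.gene_ids[g]!r} "
                f"in sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def gene_values(self, gene_id: str) -> pd.Series:
        """Expression of one gene across samples."""
        try:
            row = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return pd.Series(self.values[row], index=self.sample_ids, name=gene_id)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class GeneSetCollection:
    """Named, non-empty gene-ID sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            dup = _first_duplicate(genes)
            if dup is not None:
                raise FormatError(f"gene set {name!r} contains duplicate gene {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


#: columns every clinical TSV must provide
CLINICAL_REQUIRED = [
    "sample_id",
    "os_days",
    "event",
    "age_years",
    "sex",
    "stage",
    "egfr_status",
    "kras_status",
    "tissue",
]

_VALID_STAGES = {"I", "II", "III", "IV"}


def collapse_stage(raw: object) -> str | None:
    """Collapse sub-staged labels (IA, IB, IIIA …) to I–IV by prefix.

    Returns ``None`` for missing/unparseable values.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip().upper()
    if text.startswith("STAGE"):
        text = text[5:].strip()
    for stage in ("IV", "III", "II", "I"):  # longest prefix first
        if text.startswith(stage):
            return stage
    return None


@dataclass
class ClinicalTable:
    """Per-sample clinical records as a typed DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing required columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        dup = _first_duplicate(list(df["sample_id"]))
        if dup is not None:
            raise FormatError(f"duplicate sample ID in clinical table: {dup!r}")

        df["os_days"] = pd.to_numeric(df["os_days"], errors="raise")
        if (df["os_days"] < 0).any():
            bad = df.loc[df["os_days"] < 0, "sample_id"].iloc[0]
            raise FormatError(f"negative os_days for sample {bad!r}")
        df["event"] = df["event"].astype(int).astype(bool)

        raw_stage = df["stage"]
        collapsed = raw_stage.map(collapse_stage)
        changed = collapsed.astype(object) != raw_stage.astype(object)
        n_warn = int((changed & raw_stage.notna()).sum())
        if n_warn:
            logger.warning("collapsed or nulled %d non-canonical stage labels", n_warn)
        df["stage"] = pd.Categorical(collapsed, categories=["I", "II", "III", "IV"], ordered=True)

        for col in ("egfr_status", "kras_status"):
            vals = df[col].astype(object).where(df[col].notna(), None)
            ok = vals.map(lambda v: v in (None, "mutation", "non-mutation", "unknown"))
            if not ok.all():
                logger.warning("coding unrecognized %s values as 'unknown'", col)
                vals = vals.where(ok, "unknown")
            df[col] = vals.fillna("unknown")

        tissues = set(df["tissue"].astype(str))
        if not tissues <= {"tumor", "normal"}:
            raise FormatError(f"tissue must be tumor|normal, got {sorted(tissues - {'tumor', 'normal'})}")

        if "paired_sample_id" in df.columns:
            by_id = df.set_index("sample_id")["tissue"]
            for sid, pid, tis in zip(df["sample_id"], df["paired_sample_id"], df["tissue"]):
                if pid is None or (isinstance(pid, float) and np.isnan(pid)) or pid == "":
                    continue
                if pid not in by_id.index:
                    raise FormatError(f"paired_sample_id {pid!r} of {sid!r} not in table")
                if by_id[pid] == tis:
                    raise FormatError(f"pair {sid!r} ~ {pid!r} has same tissue {tis!r}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def tumor_samples(self) -> list[str]:
        return list(self.data.loc[self.data["tissue"] == "tumor", "sample_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """(tumor_id, normal_id) pairs, each pair reported once."""
        if "paired_sample_id" not in self.data.columns:
            return []
        out = []
        for _, row in self.data.iterrows():
            pid = row.get("paired_sample_id")
            if row["tissue"] == "tumor" and isinstance(pid, str) and pid:
                out.append((row["sample_id"], pid))
        return out


def _first_duplicate(items: list) -> object | None:
    seen: set = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene IDs, header sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise FormatError(f"{path}: duplicated gene row {dup!r}")
    dup = _first_duplicate(list(df.columns))
    if dup is not None:
        raise FormatError(f"{path}: duplicated sample column {dup!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise FormatError(f"{path}: non-numeric value for gene {gene!r} in sample {col!r}")
        df[col] = numeric
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError(f"{path}: expression TSV needs at least 2 genes and 2 samples")
    try:
        return ExpressionMatrix.from_frame(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2…`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("%s:%d: set %s had duplicate genes, deduplicated", path, lineno, name)
            if not deduped:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "paired_sample_id": str})
    try:
        return ClinicalTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_clinical_tsv(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df["event"] = df["event"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments skipped."""
    out = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_results_table(records, path, sort_by: str | None = None) -> None:
    """Write result records to a deterministic TSV (floats at 6 sig. digits).

    ``records`` may be a DataFrame or a list of dicts sharing a schema; rows
    are sorted by ``sort_by`` (default: the first column) so repeated runs
    produce byte-identical files.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if len(df):
        key = sort_by if sort_by is not None else df.columns[0]
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
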