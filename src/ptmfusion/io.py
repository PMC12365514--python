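"""Readers and writers for the pipeline's plain-text formats.

Associations, expression tables and score matrices travel as TSV; protein
sequences as FASTA (via Biopython); reports as JSON; run configuration as
YAML. Readers validate rather than coerce: NaNs, ragged rows and
non-numeric cells are rejected with coordinates.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .datatypes import AssociationMatrix, ExpressionDataset, ScoreMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_association_tsv",
    "write_association_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_scores_tsv",
    "write_scores_tsv",
    "robust_scale",
    "load_run_config",
    "dump_run_config",
]

logger = logging.getLogger("ptmfusion")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA; the ID is the first whitespace token of the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _strip(series: pd.Series, uppercase: bool) -> pd.Series:
    out = series.astype(str).str.strip()
    return out.str.upper() if uppercase else out


def read_association_tsv(
    path: str | Path,
    protein_col: str | int = 0,
    disease_col: str | int = 1,
    site_col: str | None = None,
    require_site: bool = False,
    uppercase_ids: bool = False,
) -> AssociationMatrix:
    """Two-column (protein, disease) TSV into a deduplicated binary matrix.

    Extra columns (PTM type, site, ...) are ignored; with ``require_site``
    rows whose ``site_col`` is empty are dropped first, mirroring the
    construction of PTM-site-restricted association sets. Provenance
    counts (rows read, duplicates collapsed, vocabulary sizes) are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"association file {path} has no data rows")

    def _col(key):
        if isinstance(key, int):
            if key >= df.shape[1]:
                raise ValueError(f"column index {key} out of range in {path}")
            return df.columns[key]
        if key not in df.columns:
            raise ValueError(f"column {key!r} missing from {path}")
        return key

    pcol, dcol = _col(protein_col), _col(disease_col)
    n_read = len(df)
    if require_site:
        if site_col is None:
            raise ValueError("require_site=True needs a site_col")
        scol = _col(site_col)
        df = df[df[scol].notna() & (df[scol].astype(str).str.strip() != "")]
    pairs = pd.DataFrame(
        {
            "protein": _strip(df[pcol], uppercase_ids),
            "disease": _strip(df[dcol], uppercase_ids),
        }
    )
    if (pairs == "").any().any() or pairs.isin(["nan"]).any().any():
        raise ValueError(f"empty protein/disease IDs in {path}")
    n_before = len(pairs)
    pairs = pairs.drop_duplicates()
    n_dupes = n_before - len(pairs)
    proteins = sorted(pairs["protein"].unique())
    diseases = sorted(pairs["disease"].unique())
    p_idx = {p: i for i, p in enumerate(proteins)}
    d_idx = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(proteins), len(diseases)))
    values[
        pairs["protein"].map(p_idx).to_numpy(),
        pairs["disease"].map(d_idx).to_numpy(),
    ] = 1.0
    logger.info(
        "read %d association rows from %s: %d unique pairs (%d duplicates), "
        "%d proteins, %d diseases",
        n_read, path, len(pairs), n_dupes, len(proteins), len(diseases),
    )
    return AssociationMatrix(values, proteins, diseases)


def write_association_tsv(assoc: AssociationMatrix, path: str | Path) -> None:
    pairs = assoc.positives()
    with open(path, "w") as fh:
        fh.write("protein\tdisease\n")
        for i, j in pairs:
            fh.write(f"{assoc.protein_ids[i]}\t{assoc.disease_ids[j]}\n")


def robust_scale(values: np.ndarray) -> np.ndarray:
    """Per-feature (x - median) / IQR with a unit floor on the IQR."""
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0)
    iqr = np.where(q75 - q25 > 1e-12, q75 - q25, 1.0)
    return (values - med) / iqr


def read_expression_tsv(
    path: str | Path,
    label_column: str = "subtype",
    orientation: str = "samples_rows",
    scale: bool = False,
    assoc_vocabulary: list[str] | None = None,
    disease_key: str | None = None,
    uppercase_ids: bool = False,
) -> ExpressionDataset:
    """Numeric sample x protein table with one label column.

    With ``orientation='samples_cols'`` the table is transposed first (the
    label row becoming the label column). ``assoc_vocabulary`` triggers
    shared-protein matching and an overlap report in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_cols":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError("orientation must be 'samples_rows' or 'samples_cols'")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} missing from {path}")
    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feat.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {feat.index[r]!r}, protein "
            f"{feat.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at sample {feat.index[r]!r}, protein "
            f"{feat.columns[c]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    if scale:
        values = robust_scale(values)
    codes, uniques = pd.factorize(raw_labels, sort=True)
    protein_ids = [
        str(c).strip().upper() if uppercase_ids else str(c).strip()
        for c in numeric.columns
    ]
    if assoc_vocabulary is not None:
        vocab = set(
            v.strip().upper() if uppercase_ids else v.strip() for v in assoc_vocabulary
        )
        shared = np.array(
            [k for k, p in enumerate(protein_ids) if p in vocab], dtype=int
        )
        logger.info(
            "expression table %s: %d proteins, %d shared with association data",
            path, len(protein_ids), shared.size,
        )
    else:
        shared = np.array([], dtype=int)
    return ExpressionDataset(
        values=values,
        sample_ids=[str(i) for i in numeric.index],
        protein_ids=protein_ids,
        labels=codes,
        shared_index=shared,
        disease_key=disease_key,
    )


def write_expression_tsv(expr: ExpressionDataset, path: str | Path,
                         label_column: str = "subtype") -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.protein_ids)
    df[label_column] = expr.labels
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_scores_tsv(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_scores_tsv(scores: ScoreMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        scores.values, index=scores.protein_ids, columns=scores.disease_ids
    )
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration

KNOWN_CONFIG_KEYS = {
    "seed", "preset", "out_dir", "psi", "gamma", "delta", "disease_key",
    "weight_mode", "extension_mode", "lagcn", "fwgcn", "synthetic", "paths",
}


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def dump_run_config(cfg: dict, path: str | Path) -> None:
    """Write the resolved-configuration snapshot every run must leave behind."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
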