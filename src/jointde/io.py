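"""Tabular readers/writers.

Canonical dialect: TSV, UTF-8, '#' comment lines; CSV is accepted by
sniffing the delimiter from the header line. Counts tables have genes in
rows (first column gene IDs, header row of sample IDs); covariate tables
have samples in rows. Every file written carries a header comment with the
tool version and a short settings hash, which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centering import CovariateMatrix
from .exceptions import ValidationError

__all__ = [
    "read_counts",
    "write_counts",
    "read_covariates",
    "write_covariates",
    "write_truth",
]


def _settings_hash(settings: dict | None) -> str:
    payload = json.dumps(settings or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_comment(settings: dict | None) -> str:
    return f"# jointde v{__version__} settings={_settings_hash(settings)}\n"


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise ValidationError(f"{path}: file is empty")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    except Exception as err:  # ragged rows, parse failures
        raise ValidationError(f"{path}: could not parse table ({err})") from err
    return df


def read_counts(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x samples count table.

    Returns (values, gene_ids, sample_ids). Duplicate IDs, non-numeric
    cells and negative entries are validation errors (the error names the
    offending row/column).
    """
    df = _read_table(path)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes}")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"{path}: non-numeric count entry ({err})") from err
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: missing or non-finite count entries")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"{path}: negative count at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return values, gene_ids, sample_ids


def write_counts(path, counts, gene_ids, sample_ids,
                 settings: dict | None = None) -> None:
    df = pd.DataFrame(np.asarray(counts), index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(settings))
        df.to_csv(fh, sep="\t")


def read_covariates(path, sample_ids: list[str]) -> CovariateMatrix:
    """Read a samples x covariates table, aligned to the counts' sample order.

    The file's sample order may differ; missing or extra samples are errors.
    """
    df = _read_table(path)
    file_ids = [str(s) for s in df.index]
    if len(set(file_ids)) != len(file_ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    missing = [s for s in sample_ids if s not in set(file_ids)]
    extra = [s for s in file_ids if s not in set(sample_ids)]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing samples {missing}")
        if extra:
            parts.append(f"unknown samples {extra}")
        raise ValidationError(f"{path}: covariates do not align: " + "; ".join(parts))
    df.index = file_ids
    df = df.loc[sample_ids]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"{path}: non-numeric covariate ({err})") from err
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: missing or non-finite covariate entries")
    return CovariateMatrix(values, sample_ids=list(sample_ids),
                           covariate_names=[str(c) for c in df.columns])


def write_covariates(path, X: CovariateMatrix,
                     settings: dict | None = None) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.covariate_names)
    df.index.name = "sample_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(settings))
        df.to_csv(fh, sep="\t")


def write_truth(path, gene_ids, truth_beta, de_labels,
                settings: dict | None = None) -> None:
    beta = np.atleast_2d(np.asarray(truth_beta))
    cols = {f"beta_{k + 1}": beta[:, k] for k in range(beta.shape[1])}
    df = pd.DataFrame({"gene_id": gene_ids, **cols, "is_de": np.asarray(de_labels)})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(settings))
        df.to_csv(fh, sep="\t", index=False)
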