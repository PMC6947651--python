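"""File readers and writers: TSV/CSV matrices, edge lists, weights, GO, VCF.

Conventions: tab is the default delimiter with comma auto-detected on read;
ids are opaque strings; every file this package writes starts with comment
lines (``#``) recording the tool version, the command line, and the master
seed, and every reader skips such lines.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .exceptions import DataError

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__


def header_lines(command: Optional[str] = None, seed: Optional[int] = None) -> str:
    lines = [f"# penirf {_version()}"]
    lines.append(f"# command: {command if command is not None else ' '.join(sys.argv)}")
    if seed is not None:
        lines.append(f"# master_seed: {seed}")
    return "\n".join(lines) + "\n"


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise DataError(f"{path}: no data lines found")


def read_matrix(
    path, features_in_rows: bool = True, impute_mean: bool = False, sep: Optional[str] = None
) -> Dataset:
    """Read a delimited matrix into a samples × features Dataset.

    With ``features_in_rows`` (the default, matching gene × sample and SNP ×
    sample layouts) the first column holds feature ids and the header row
    holds sample ids; the matrix is transposed internally.  NaN cells are a
    hard error unless ``impute_mean`` is set, which fills each feature's mean.
    """
    sep = sep or _sniff_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, comment="#", index_col=0, header=0)
    except Exception as exc:  # pandas raises many parser subclasses
        raise DataError(f"{path}: cannot parse matrix: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise DataError(f"{path}: duplicate id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise DataError(f"{path}: duplicate id {dup!r}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise DataError(
                f"{path}: non-numeric value {bad.iloc[0]!r} "
                f"at row {bad.index[0]!r}, column {col!r}"
            )
    if features_in_rows:
        frame = frame.T
    if frame.isna().any().any():
        if not impute_mean:
            col = frame.columns[frame.isna().any()][0]
            raise DataError(
                f"{path}: missing value in column {col!r} "
                "(pass impute_mean/--impute-mean to fill feature means)"
            )
        frame = frame.fillna(frame.mean())
    return Dataset.from_frame(frame.astype(np.float64))


def write_matrix(
    data, path, features_in_rows: bool = True, command: Optional[str] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a Dataset or samples × features DataFrame as headered TSV."""
    frame = data.to_frame() if isinstance(data, Dataset) else pd.DataFrame(data)
    if features_in_rows:
        frame = frame.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(command, seed))
        frame.to_csv(fh, sep="\t")


def write_edges(edges: pd.DataFrame, path, command=None, seed=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(command, seed))
        edges.to_csv(fh, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, comment="#")


def write_weights(feature_ids: Sequence[str], weights, path, command=None, seed=None) -> None:
    """2-column (feature_id, weight) TSV at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(command, seed))
        fh.write("feature_id\tweight\n")
        for fid, w in zip(feature_ids, np.asarray(weights, dtype=np.float64)):
            fh.write(f"{fid}\t{float(w)!r}\n")


def read_weights(path, feature_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Read a weights file back, optionally aligned to a feature-id order."""
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    frame["feature_id"] = frame["feature_id"].astype(str)
    if feature_ids is None:
        return frame["weight"].to_numpy(dtype=np.float64)
    lookup = dict(zip(frame["feature_id"], frame["weight"]))
    missing = [f for f in feature_ids if str(f) not in lookup]
    if missing:
        raise DataError(f"{path}: weights missing for feature {missing[0]!r}")
    return np.array([lookup[str(f)] for f in feature_ids], dtype=np.float64)


write_importance = write_weights  # same 2-column dialect, (feature_id, score)


def read_annotations(path) -> pd.DataFrame:
    """Read gene↔term annotations: 2-column TSV or GAF 2.x.

    GAF is detected by ``!`` comment lines or >= 15 tab-separated columns;
    columns 3 (DB object symbol) and 5 (GO id) are kept.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = ""
        for line in fh:
            if line.startswith(("#",)) or not line.strip():
                continue
            first = line
            break
    is_gaf = first.startswith("!") or len(first.rstrip("\n").split("\t")) >= 15
    if is_gaf:
        frame = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        frame = frame.iloc[:, [2, 4]]
        frame.columns = ["gene_id", "term_id"]
    else:
        sep = _sniff_sep(path)
        frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
        if list(frame.columns[:2]) != ["gene_id", "term_id"]:
            # headerless 2-column file
            frame = pd.read_csv(path, sep=sep, comment="#", header=None, dtype=str)
            frame.columns = ["gene_id", "term_id"]
    return frame.drop_duplicates().reset_index(drop=True)


def read_vcf_dosage(path) -> pd.DataFrame:
    """Read GT dosages from a VCF into a SNP × sample DataFrame.

    Only biallelic records are kept (multiallelic skips are counted and
    logged); genotypes map 0/0→0, 0/1 or 1/0→1, 1/1→2, missing→NaN.  SNP ids
    are ``CHROM:POS:REF:ALT``; the skip count is stored in
    ``frame.attrs["n_multiallelic_skipped"]``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids = [], []
    skipped = 0
    for record in vcf:
        if len(record.ALT) != 1:
            skipped += 1
            continue
        gt = record.gt_types.astype(float)  # 0=hom-ref,1=het,2=hom-alt,3=unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}")
    vcf.close()
    if skipped:
        logger.info("read_vcf_dosage: skipped %d multiallelic record(s)", skipped)
    frame = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(samples))),
        index=ids,
        columns=samples,
    )
    frame.attrs["n_multiallelic_skipped"] = skipped
    return frame


def write_score_report(report, path, command=None, seed=None) -> None:
    """ScoreReport as a 1-row TSV plus the full null-score vector alongside."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(command, seed))
        report.to_frame().to_csv(fh, sep="\t", index=False)
    null_path = path.with_suffix(path.suffix + ".null.tsv")
    with open(null_path, "w", encoding="utf-8") as fh:
        fh.write(header_lines(command, seed))
        fh.write("null_score\n")
        for s in report.null_scores:
            fh.write(f"{float(s)!r}\n")
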