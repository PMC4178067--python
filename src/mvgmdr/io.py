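"""Readers and writers for genotype, phenotype, covariate and result files.

Two genotype dialects are supported: PLINK ``.raw`` (the additive recode
produced by ``plink --recode A``: header ``FID IID PAT MAT SEX PHENOTYPE``
followed by one column per SNP with values 0/1/2/NA) and a plain TSV with a
``sample_id`` column.  Phenotypes and covariates are TSVs keyed by
``sample_id`` and are re-ordered to a supplied sample order, dropping (and
counting) unmatched rows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MISSING, CovariateMatrix, GenotypeMatrix, PhenotypeSet
from .errors import AlignmentError, FormatError

log = logging.getLogger(__name__)

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _raw_header_columns(path, whitespace: bool) -> list[str]:
    """First-line column names before pandas mangles duplicates."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split() if whitespace else header.split("\t")
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate column names {sorted(dupes)}")
    return cols


def _coerce_genotype_block(df: pd.DataFrame, sample_ids, locus_ids, path) -> GenotypeMatrix:
    values = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        raw = df[col]
        missing = raw.isna() | raw.astype(str).str.upper().isin(["NA", "NAN", ""])
        num = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = num.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: genotype token {raw.iloc[i]!r} at row {i + 1}, "
                f"column {col!r} is not 0/1/2/NA"
            )
        ok = ~missing.to_numpy()
        vals = num.to_numpy(dtype=float)
        if ok.any():
            nonint = ok & (vals != np.floor(vals))
            if nonint.any():
                i = int(np.flatnonzero(nonint)[0])
                raise FormatError(
                    f"{path}: genotype token {raw.iloc[i]!r} at row {i + 1}, "
                    f"column {col!r} is not an integer code"
                )
            values[ok, j] = vals[ok].astype(np.int8)
    return GenotypeMatrix(values, list(locus_ids), list(sample_ids))


def read_genotypes(path, format: str = "plink_raw") -> GenotypeMatrix:
    """Read an additively coded genotype matrix.

    ``format='plink_raw'`` expects the PLINK additive recode dialect;
    ``format='tsv'`` expects a ``sample_id`` column followed by one column
    per locus.  Missing calls (``NA``) map to :data:`~mvgmdr.datamodel.MISSING`.
    """
    path = Path(path)
    if format == "plink_raw":
        _raw_header_columns(path, whitespace=True)
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        if list(df.columns[: len(_RAW_META)]) != _RAW_META:
            raise FormatError(
                f"{path}: malformed .raw header; expected leading columns {_RAW_META}, "
                f"got {list(df.columns[:6])}"
            )
        snp_cols = df.columns[len(_RAW_META) :]
        if len(snp_cols) == 0:
            raise FormatError(f"{path}: no SNP columns after the .raw metadata block")
        iid = df["IID"].astype(str)
        sample_ids = iid if iid.is_unique else df["FID"].astype(str) + "_" + iid
        return _coerce_genotype_block(df[snp_cols], sample_ids.tolist(), snp_cols, path)
    if format == "tsv":
        _raw_header_columns(path, whitespace=False)
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0] != "sample_id":
            raise FormatError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
        return _coerce_genotype_block(
            df[df.columns[1:]], df["sample_id"].tolist(), df.columns[1:], path
        )
    raise FormatError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path, format: str = "plink_raw") -> None:
    """Write a genotype matrix in either dialect (round-trips exactly)."""
    path = Path(path)
    block = pd.DataFrame(
        np.where(G.values == MISSING, None, G.values), columns=G.locus_ids, dtype=object
    )
    if format == "plink_raw":
        meta = pd.DataFrame(
            {
                "FID": G.sample_ids,
                "IID": G.sample_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        pd.concat([meta, block], axis=1).to_csv(path, sep=" ", index=False, na_rep="NA")
    elif format == "tsv":
        block.insert(0, "sample_id", G.sample_ids)
        block.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        raise FormatError(f"unknown genotype format {format!r}")


def _read_numeric_table(path, what: str):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    ids = df["sample_id"].astype(str).tolist()
    cols = list(df.columns[1:])
    values = np.empty((len(df), len(cols)))
    for j, col in enumerate(cols):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric {what} value {df[col].iloc[i]!r} "
                f"at row {i + 1}, column {col!r}"
            )
        values[:, j] = num.to_numpy()
    return ids, cols, values


def _align(ids, values, sample_order, path, what):
    if sample_order is None:
        return ids, values
    index = {s: i for i, s in enumerate(ids)}
    keep = [s for s in sample_order if s in index]
    if not keep:
        raise AlignmentError(f"{path}: no overlapping samples with the genotype matrix")
    dropped = len(ids) - len(keep)
    if dropped or len(keep) < len(sample_order):
        log.info(
            "%s: aligned %d samples (%d %s rows dropped, %d target samples absent)",
            path, len(keep), dropped, what, len(sample_order) - len(keep),
        )
    rows = [index[s] for s in keep]
    return keep, values[rows]


def read_phenotypes(path, sample_order=None) -> PhenotypeSet:
    """Read a phenotype TSV, optionally re-ordered to ``sample_order``."""
    ids, cols, values = _read_numeric_table(path, "trait")
    ids, values = _align(ids, values, sample_order, path, "phenotype")
    return PhenotypeSet(values, cols)


def read_covariates(path, sample_order=None) -> CovariateMatrix:
    """Read a covariate TSV, optionally re-ordered to ``sample_order``."""
    ids, cols, values = _read_numeric_table(path, "covariate")
    ids, values = _align(ids, values, sample_order, path, "covariate")
    return CovariateMatrix(values, cols)


def _result_record(res, significance=None) -> dict:
    rec = {
        "size": int(res.size),
        "best_subset": list(res.final_locus_ids),
        "cvc": int(res.cvc),
        "mean_train_accuracy": float(res.mean_train_accuracy),
        "mean_test_accuracy": float(res.mean_test_accuracy),
        "winner_mean_test_accuracy": float(res.winner_mean_test_accuracy),
        "n_subsets": int(res.n_subsets),
    }
    if significance and res.size in significance:
        rec["p_values"] = {k: float(v) for k, v in significance[res.size].items()}
    else:
        rec["p_values"] = {}
    return rec


def write_results(search_results, significance_results, out_dir) -> tuple[Path, Path]:
    """Serialize per-size search results as JSON + a human-readable TSV.

    ``significance_results`` maps model size -> {p-value name -> value} and may
    be ``None``.  Returns the two paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = [_result_record(r, significance_results) for r in search_results]
    json_path = out_dir / "results.json"
    with open(json_path, "w") as fh:
        json.dump(records, fh, indent=2)

    pnames = sorted({k for rec in records for k in rec["p_values"]})
    rows = []
    for rec in records:
        row = {
            "size": rec["size"],
            "best_subset": ",".join(rec["best_subset"]),
            "CVC": rec["cvc"],
            "train_accuracy": f"{rec['mean_train_accuracy']:.4f}",
            "test_accuracy": f"{rec['mean_test_accuracy']:.4f}",
        }
        for p in pnames:
            v = rec["p_values"].get(p)
            row[p] = "" if v is None else f"{v:.3e}"
        rows.append(row)
    tsv_path = out_dir / "results.tsv"
    cols = ["size", "best_subset", "CVC", "train_accuracy", "test_accuracy", *pnames]
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def load_results(json_path) -> list[dict]:
    """Re-load the JSON emitted by :func:`write_results`."""
    with open(json_path) as fh:
        return json.load(fh)
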