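"""File-format codecs: dosage/phenotype/sumstats/panel TSVs and dosage VCF.

Column contracts (all 1-based coordinates, tab-separated, header row):

- dosages: ``variant_id chrom pos EA OA`` then one column per sample holding
  the expected allele count in [0, 2];
- phenotypes: ``sample_id`` plus numeric columns;
- sumstats: ``variant_id chrom pos EA OA EAF info phenotype beta se p n``;
- panels: ``variant_id trait``;
- loci: BED-like ``chrom start end lead members traits`` (closed intervals).

Malformed rows are rejected with their line numbers.  VCF export carries the
dosage in a ``DS`` FORMAT field; import uses cyvcf2 when installed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .assoc import SUMSTATS_COLUMNS

__all__ = [
    "read_dosages",
    "write_dosages",
    "read_phenotypes",
    "write_phenotypes",
    "read_sumstats",
    "write_sumstats",
    "read_panel",
    "write_panel",
    "write_loci",
    "write_vcf",
    "read_vcf",
]

_DOSAGE_META = ["variant_id", "chrom", "pos", "EA", "OA"]


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_dosages(path: str, dosages: np.ndarray, variants: pd.DataFrame, sample_ids: list[str]) -> None:
    d = np.asarray(dosages, dtype=float)
    out = variants[_DOSAGE_META].copy()
    body = pd.DataFrame(d.T, columns=list(sample_ids))
    pd.concat([out.reset_index(drop=True), body], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosages(path: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _DOSAGE_META, path)
    sample_ids = [c for c in df.columns if c not in _DOSAGE_META]
    body = df[sample_ids].apply(pd.to_numeric, errors="coerce")
    bad_rows = body.isna().all(axis=1)
    if bad_rows.any():
        lines = (np.flatnonzero(bad_rows) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric dosage rows at lines {lines[:10]}")
    d = body.to_numpy(dtype=float).T
    if np.nanmin(d) < 0 or np.nanmax(d) > 2:
        raise ValueError(f"{path}: dosages outside [0, 2]")
    variants = df[_DOSAGE_META].copy()
    variants["pos"] = variants["pos"].astype(int)
    return d, variants, sample_ids


def write_phenotypes(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id"], path)
    return df


def write_sumstats(path: str, sumstats: pd.DataFrame) -> None:
    _require_columns(sumstats, SUMSTATS_COLUMNS, path)
    sumstats[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SUMSTATS_COLUMNS, path)
    for col, line0 in (("p", 2),):
        bad = df[col].isna() | (df[col] <= 0) | (df[col] > 1)
        if bad.any():
            raise ValueError(f"{path}: invalid p-values at lines {(np.flatnonzero(bad) + 2).tolist()[:10]}")
    return df


def write_panel(path: str, panel: pd.DataFrame) -> None:
    _require_columns(panel, ["variant_id", "trait"], path)
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["variant_id", "trait"], path)
    return df


def write_loci(path: str, loci_table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# closed 1-based intervals: [start, end]\n")
        loci_table.to_csv(fh, sep="\t", index=False)


def write_vcf(path: str, dosages: np.ndarray, variants: pd.DataFrame, sample_ids: list[str]) -> None:
    """Minimal VCF 4.2 export with dosage in a DS FORMAT field."""
    d = np.asarray(dosages, dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j, rec in enumerate(variants.itertuples(index=False)):
            # EA is the counted (ALT) allele
            fields = [str(rec.chrom), str(int(rec.pos)), rec.variant_id, rec.OA, rec.EA, ".", "PASS", ".", "DS"]
            fields += [f"{x:.6g}" if not np.isnan(x) else "." for x in d[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a dosage VCF (DS FORMAT field) via cyvcf2."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise ValueError(f"{path}: record {rec.ID} lacks a DS field")
        cols.append(np.asarray(ds, dtype=float).reshape(-1))
        rows.append(
            {
                "variant_id": rec.ID,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "EA": rec.ALT[0],
                "OA": rec.REF,
            }
        )
    d = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return d, pd.DataFrame(rows), sample_ids


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
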