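"""Tabular readers and writers plus the flat key-value config format.

One dialect everywhere: tab-separated, UTF-8, mandatory header row, ``NA``
as the missing token, ``.`` as the decimal separator.  Floats are written
with 17 significant digits so write/read round-trips are bit-exact.

An expression matrix is stored as three files sharing a stem:

* ``<stem>.tsv``          — gene_id column then one log10-ratio column per
  sample, headed by sample ids;
* ``<stem>.lambda.tsv``   — same layout for the lambda values (optional);
* ``<stem>.samples.tsv``  — sample metadata (sample_id, strain, replicate,
  sample_index, dye_flip, od600).

Growth curves travel as CSV with columns strain,replicate,time_h,od600;
morphology, metabolite and annotation tables as plain TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenomeAnnotation, GrowthCurve, SampleMeta

__all__ = [
    "read_growth_curves",
    "write_growth_curves",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_morphology",
    "write_morphology",
    "read_metabolites",
    "write_metabolites",
    "read_config",
]

log = logging.getLogger(__name__)

NA = "NA"
_FLOAT_FMT = "%.17g"


def _fmt(v: float) -> str:
    return NA if not np.isfinite(v) else _FLOAT_FMT % v


# ---------------------------------------------------------------------------
# Growth curves (CSV)
# ---------------------------------------------------------------------------

def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Read growth curves from CSV (strain,replicate,time_h,od600)."""
    df = pd.read_csv(path, na_values=[NA], float_precision="round_trip")
    required = {"strain", "replicate", "time_h", "od600"}
    if not required <= set(df.columns):
        raise ValueError(f"growth CSV must have columns {sorted(required)}")
    curves = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                replicate=str(rep),
                time_h=grp["time_h"].to_numpy(float),
                od600=grp["od600"].to_numpy(float),
            )
        )
    return curves


def write_growth_curves(curves: list[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.time_h, c.od600):
            rows.append({"strain": c.strain, "replicate": c.replicate, "time_h": t, "od600": od})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Expression matrices (TSV triplet)
# ---------------------------------------------------------------------------

def _companion_paths(path: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix == ".tsv" else p
    return Path(str(stem) + ".tsv"), Path(str(stem) + ".lambda.tsv"), Path(str(stem) + ".samples.tsv")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix, its lambda companion and its sample metadata."""
    ratio_path, lambda_path, samples_path = _companion_paths(path)
    ids = [s.sample_id for s in matrix.samples]

    def write_table(p: Path, data: np.ndarray) -> None:
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("gene_id\t" + "\t".join(ids) + "\n")
            for g, row in zip(matrix.gene_ids, data):
                fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")

    write_table(ratio_path, matrix.log10_ratio)
    if matrix.lam is not None:
        write_table(lambda_path, matrix.lam)
    with open(samples_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tstrain\treplicate\tsample_index\tdye_flip\tod600\n")
        for s in matrix.samples:
            fh.write(
                f"{s.sample_id}\t{s.strain}\t{s.replicate}\t{s.sample_index}\t"
                f"{int(s.dye_flip)}\t{_FLOAT_FMT % s.od600}\n"
            )


def _read_value_table(path: Path, what: str) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise ValueError(f"{what} table must start with a 'gene_id' header column")
        sample_ids = header[1:]
        genes: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for line_no, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{what} row {line_no}: expected {len(header)} fields, got {len(fields)}")
            g = fields[0]
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r} in {what} table")
            seen.add(g)
            genes.append(g)
            row = []
            for j, cell in enumerate(fields[1:], start=2):
                if cell == NA:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {line_no}, column {j} of {what} table"
                    ) from None
            rows.append(row)
    return genes, sample_ids, np.array(rows, dtype=float).reshape(len(genes), len(sample_ids))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression_matrix`.

    The lambda companion is optional; negative lambda values are rejected.
    Samples are re-sorted to the canonical order on construction.  A parse
    report (genes read, missing cells) is logged.
    """
    ratio_path, lambda_path, samples_path = _companion_paths(path)
    genes, sample_ids, ratios = _read_value_table(ratio_path, "ratio")
    meta = pd.read_csv(samples_path, sep="\t", dtype={"strain": str, "replicate": str},
                       float_precision="round_trip")
    by_id: dict[str, SampleMeta] = {}
    for _, r in meta.iterrows():
        s = SampleMeta(
            strain=str(r["strain"]),
            replicate=str(r["replicate"]),
            sample_index=int(r["sample_index"]),
            dye_flip=bool(int(r["dye_flip"])),
            od600=float(r["od600"]),
        )
        by_id[s.sample_id] = s
    missing_meta = [sid for sid in sample_ids if sid not in by_id]
    if missing_meta:
        raise ValueError(f"samples missing from metadata table: {missing_meta}")
    samples = [by_id[sid] for sid in sample_ids]

    lam = None
    if lambda_path.exists():
        lgenes, lids, lam = _read_value_table(lambda_path, "lambda")
        if lgenes != genes or lids != sample_ids:
            raise ValueError("lambda table does not align with the ratio table")
        if np.any(lam[np.isfinite(lam)] < 0):
            raise ValueError("lambda values must be >= 0")
    matrix = ExpressionMatrix(genes, samples, ratios, lam)
    log.info(
        "read expression matrix %s: %d genes x %d samples, %d missing cells",
        ratio_path, matrix.n_genes, matrix.n_samples, int(np.isnan(ratios).sum()),
    )
    return matrix


# ---------------------------------------------------------------------------
# Annotation, morphology, metabolites (TSV)
# ---------------------------------------------------------------------------

def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\treplicon\n")
        for g in sorted(annotation.replicon_of):
            fh.write(f"{g}\t{annotation.replicon_of[g]}\n")


def read_annotation(path: str | Path, total_genes: int | None = None) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "replicon"} <= set(df.columns):
        raise ValueError("annotation TSV must have columns gene_id, replicon")
    return GenomeAnnotation(dict(zip(df["gene_id"], df["replicon"])), total_genes=total_genes)


_MORPH_COLS = [
    "cell_id", "timepoint", "area", "perimeter", "circularity",
    "major_axis", "minor_axis", "mean_intensity",
]


def write_morphology(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _MORPH_COLS if c in table.columns] + [
        c for c in table.columns if c not in _MORPH_COLS
    ]
    table[cols].to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_morphology(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], float_precision="round_trip")
    required = {"cell_id", "timepoint", "circularity"}
    if not required <= set(df.columns):
        raise ValueError(f"morphology TSV must have columns {sorted(required)}")
    return df


def write_metabolites(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_metabolites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], float_precision="round_trip")
    required = {"feature_id", "phase", "replicate", "abundance"}
    if not required <= set(df.columns):
        raise ValueError(f"metabolite TSV must have columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Config: flat key = value text
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file.

    Blank lines and ``#`` comments are ignored; keys are case-sensitive;
    later assignments override earlier ones.  All thresholds, seeds and
    phase-fraction parameters of a pipeline run live here.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {line_no}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if not key:
                raise ValueError(f"config line {line_no}: empty key")
            out[key] = value
    return out
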