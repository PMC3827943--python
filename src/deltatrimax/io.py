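"""File formats: long/matrix TSV tensors, JSON results, GMT gene sets."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .algorithm import DataError, TrimaxParams, TrimaxResult
from .tensor import ExpressionTensor, Tricluster, msr as compute_msr

__all__ = [
    "read_long_tsv",
    "write_long_tsv",
    "read_matrix_stack",
    "write_result",
    "read_result",
    "read_gmt",
    "file_checksum",
]

RESULT_FORMAT = "deltatrimax-result"
RESULT_VERSION = 1
LONG_COLUMNS = ["gene_id", "sample_id", "time", "value"]


def read_long_tsv(path) -> ExpressionTensor:
    """Read a long-format TSV (gene_id, sample_id, time, value).

    Axis labels are the sorted unique gene/sample ids and ascending numeric
    times.  Combinations absent from the file become missing-mask cells;
    duplicated combinations with conflicting values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str},
                     float_precision="round_trip")
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing columns {missing_cols}")
    for col in ("time", "value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any() and col == "time":
            raise DataError(f"{path}: non-numeric entries in column {col!r}")
    if df["value"].isna().any():
        raise DataError(f"{path}: non-numeric entries in column 'value'")

    dup = df.duplicated(subset=["gene_id", "sample_id", "time"], keep=False)
    if dup.any():
        conflicts = (df[dup].groupby(["gene_id", "sample_id", "time"])["value"]
                     .nunique())
        conflicts = conflicts[conflicts > 1]
        if len(conflicts):
            keys = list(conflicts.index[:5])
            raise DataError(f"{path}: conflicting duplicate rows for keys "
                            f"{keys}")
        df = df.drop_duplicates(subset=["gene_id", "sample_id", "time"])

    genes = sorted(df["gene_id"].unique())
    samples = sorted(df["sample_id"].unique())
    times = sorted(df["time"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    ti = {t: k for k, t in enumerate(times)}

    values = np.full((len(genes), len(samples), len(times)), np.nan)
    values[df["gene_id"].map(gi).to_numpy(),
           df["sample_id"].map(si).to_numpy(),
           df["time"].map(ti).to_numpy()] = df["value"].to_numpy()
    mask = np.isnan(values)
    return ExpressionTensor(values, tuple(genes), tuple(samples),
                            tuple(times), missing_mask=mask)


def write_long_tsv(tensor: ExpressionTensor, path) -> None:
    """Write a tensor in long format; masked cells are omitted."""
    rows = []
    mask = tensor.missing_mask
    for i, g in enumerate(tensor.gene_ids):
        for j, s in enumerate(tensor.sample_ids):
            for k, t in enumerate(tensor.time_labels):
                if not mask[i, j, k]:
                    rows.append((g, s, t, tensor.values[i, j, k]))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_matrix_stack(paths: Sequence, time_labels: Sequence[float]
                      ) -> ExpressionTensor:
    """Stack per-time gene x sample TSV matrices into a tensor.

    Every file must carry the same gene/sample labels (any row order);
    matrices are aligned by label.  A label present in one file but not
    another is an error — there is no silent intersection.
    """
    if len(paths) != len(time_labels):
        raise DataError("one matrix file per time label required")
    frames = [pd.read_csv(p, sep="\t", index_col=0) for p in paths]
    genes = sorted(frames[0].index.astype(str))
    samples = sorted(frames[0].columns.astype(str))
    for p, f in zip(paths, frames):
        f.index = f.index.astype(str)
        f.columns = f.columns.astype(str)
        if sorted(f.index) != genes or sorted(f.columns) != samples:
            extra = set(f.index).symmetric_difference(genes) \
                or set(f.columns).symmetric_difference(samples)
            raise DataError(f"{p}: row/column headers disagree with "
                            f"{paths[0]} (first discrepancy: "
                            f"{sorted(extra)[:3]})")
    order = np.argsort(np.asarray(time_labels, dtype=float))
    values = np.stack(
        [frames[int(o)].loc[genes, samples].to_numpy(dtype=float)
         for o in order], axis=2)
    times = tuple(float(time_labels[int(o)]) for o in order)
    mask = np.isnan(values)
    return ExpressionTensor(values, tuple(genes), tuple(samples), times,
                            missing_mask=mask)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _params_dict(p: TrimaxParams) -> dict:
    return {"delta": p.delta, "lam": p.lam,
            "deletion_guard": p.deletion_guard,
            "max_triclusters": p.max_triclusters,
            "min_genes": p.min_genes, "min_samples": p.min_samples,
            "min_times": p.min_times, "seed": p.seed}


def write_result(result: TrimaxResult, path,
                 tensor: ExpressionTensor | None = None,
                 manifest: dict | None = None) -> None:
    """Serialize a run to JSON (config echo, labelled triclusters, MSRs)."""
    doc = {
        "format": RESULT_FORMAT,
        "version": RESULT_VERSION,
        "config": _params_dict(result.params),
        "manifest": manifest or {},
        "triclusters": [],
    }
    for tc in result.triclusters:
        entry = {
            "gene_idx": list(tc.gene_idx),
            "sample_idx": list(tc.sample_idx),
            "time_idx": list(tc.time_idx),
            "msr": tc.msr,
            "volume": tc.volume,
        }
        if tensor is not None:
            entry["genes"] = list(tensor.gene_labels(tc.gene_idx))
            entry["samples"] = list(tensor.sample_labels(tc.sample_idx))
            entry["times"] = list(tensor.time_values(tc.time_idx))
        doc["triclusters"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_result(path, tensor: ExpressionTensor | None = None,
                verify_msr: bool = True) -> TrimaxResult:
    """Load a result JSON; with a tensor, stored MSRs are re-verified."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != RESULT_FORMAT:
        raise DataError(f"{path}: not a {RESULT_FORMAT} file")
    if doc.get("version") != RESULT_VERSION:
        raise DataError(f"{path}: result version {doc.get('version')} not "
                        f"supported (expected {RESULT_VERSION})")
    params = TrimaxParams(**doc["config"])
    triclusters = []
    for entry in doc["triclusters"]:
        tc = Tricluster(tuple(entry["gene_idx"]), tuple(entry["sample_idx"]),
                        tuple(entry["time_idx"]), msr=entry["msr"])
        if tensor is not None and verify_msr:
            recomputed = compute_msr(tensor, tc)
            if not np.isclose(recomputed, tc.msr, rtol=1e-6, atol=1e-9):
                raise DataError(
                    f"{path}: stored MSR {tc.msr} disagrees with tensor "
                    f"recomputation {recomputed}")
        triclusters.append(tc)
    return TrimaxResult(triclusters=triclusters, params=params)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}: GMT line with fewer than 3 fields: "
                            f"{line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
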