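"""Readers and writers for band matrices, metadata, FASTA and reports.

Band-matrix format: CSV/TSV with a ``locus_id`` column followed by two
columns per sample, ``<sample_id>__HpaII`` and ``<sample_id>__MspI``, with
strictly 0/1 cells.  Metadata: CSV with columns sample_id, genotype,
condition, timepoint_das, replicate.  All report writers emit deterministic
row/column order (loci in input order, patterns A->P, classes a->i), a
trailing newline, and sorted JSON keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import BisulfiteSummary
from .patterns import PATTERN_ORDER, PATTERNS, TransitionSummary
from .recovery import RECOVERY_CLASS_ORDER, RecoverySummary
from .states import MethylationSummary, MsapDataset, SampleMeta

__all__ = [
    "read_band_matrix",
    "write_band_matrix",
    "read_fasta",
    "write_fasta",
    "write_methylation_report",
    "write_transition_report",
    "write_recovery_report",
    "write_bisulfite_report",
]

_HPAII_SUFFIX = "__HpaII"
_MSPI_SUFFIX = "__MspI"


class ParseError(ValueError):
    """Malformed input file; message names the file and offending cell."""


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_band_matrix(path: str | Path, meta_path: str | Path) -> MsapDataset:
    """Read a band matrix plus metadata into a validated :class:`MsapDataset`."""
    df = _read_table(path)
    if df.columns[0] != "locus_id":
        raise ParseError(f"{path}: first column must be 'locus_id'")
    locus_ids = df["locus_id"].tolist()
    if len(set(locus_ids)) != len(locus_ids):
        dupes = df["locus_id"][df["locus_id"].duplicated()].tolist()
        raise ParseError(f"{path}: duplicate locus ids {dupes[:3]}")

    lane_cols = list(df.columns[1:])
    sample_ids: list[str] = []
    for col in lane_cols:
        if col.endswith(_HPAII_SUFFIX):
            sid = col[: -len(_HPAII_SUFFIX)]
            if f"{sid}{_MSPI_SUFFIX}" not in lane_cols:
                raise ParseError(f"{path}: unpaired lane — {col} has no MspI mate")
            sample_ids.append(sid)
        elif col.endswith(_MSPI_SUFFIX):
            sid = col[: -len(_MSPI_SUFFIX)]
            if f"{sid}{_HPAII_SUFFIX}" not in lane_cols:
                raise ParseError(f"{path}: unpaired lane — {col} has no HpaII mate")
        else:
            raise ParseError(
                f"{path}: column {col!r} is not '<sample_id>__HpaII' or '<sample_id>__MspI'"
            )

    for col in lane_cols:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-binary cell {df[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )

    meta_df = _read_table(meta_path)
    required = {"sample_id", "genotype", "condition", "timepoint_das"}
    missing = required - set(meta_df.columns)
    if missing:
        raise ParseError(f"{meta_path}: missing columns {sorted(missing)}")
    meta_by_id = {}
    for _, row in meta_df.iterrows():
        rep = row.get("replicate")
        meta_by_id[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            genotype=row["genotype"],
            condition=row["condition"],
            timepoint_das=int(row["timepoint_das"]),
            replicate=int(rep) if rep not in (None, "", np.nan) and pd.notna(rep) else None,
        )

    samples = []
    for sid in sample_ids:
        if sid not in meta_by_id:
            raise ParseError(f"{path}: sample {sid!r} missing from {meta_path}")
        samples.append(meta_by_id[sid])

    presence = np.stack(
        [
            np.stack(
                [
                    df[f"{sid}{_HPAII_SUFFIX}"].astype(np.uint8).to_numpy(),
                    df[f"{sid}{_MSPI_SUFFIX}"].astype(np.uint8).to_numpy(),
                ],
                axis=1,
            )
            for sid in sample_ids
        ],
        axis=1,
    )
    return MsapDataset(locus_ids=locus_ids, samples=samples, presence=presence)


def write_band_matrix(
    dataset: MsapDataset, path: str | Path, meta_path: str | Path
) -> None:
    """Write a dataset back to matrix + metadata CSV (round-trips exactly)."""
    data: dict[str, object] = {"locus_id": dataset.locus_ids}
    for j, s in enumerate(dataset.samples):
        data[f"{s.sample_id}{_HPAII_SUFFIX}"] = dataset.presence[:, j, 0]
        data[f"{s.sample_id}{_MSPI_SUFFIX}"] = dataset.presence[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)

    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "condition": s.condition,
                "timepoint_das": s.timepoint_das,
                "replicate": s.replicate if s.replicate is not None else "",
            }
            for s in dataset.samples
        ]
    )
    meta.to_csv(meta_path, index=False)


def read_fasta(path: str | Path, ref_id: str | None = None) -> tuple[str, dict[str, str]]:
    """Read a FASTA of reference + clone sequences.

    The record named ``ref_id`` (or the first record when omitted) is the
    untreated reference; all other records are bisulfite clones.  Returns
    ``(reference_id, {id: sequence})`` with the reference included.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    if ref_id is None:
        ref_id = next(iter(records))
    if ref_id not in records:
        raise ParseError(f"{path}: reference id {ref_id!r} not found")
    return ref_id, records


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _write_json(payload: object, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_methylation_report(
    summaries: list[MethylationSummary], path: str | Path, fmt: str = "csv"
) -> None:
    """Write per-sample summaries in the conventional summary-table layout."""
    path = Path(path)
    rows = [
        {
            "sample_id": s.sample_id,
            "I": s.n_type["I"],
            "II": s.n_type["II"],
            "III": s.n_type["III"],
            "IV": s.n_type["IV"],
            "total_amplified": s.n_total,
            "total_methylated": s.n_methylated,
            "fully_methylated": s.n_fully,
            "msap_pct": round(s.msap_pct, 2),
            "fully_pct": round(s.fully_pct, 2),
            "hemi_pct": round(s.hemi_pct, 2),
        }
        for s in summaries
    ]
    if fmt == "json":
        _write_json(rows, path)
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def write_transition_report(
    summary: TransitionSummary, path: str | Path, fmt: str = "csv"
) -> None:
    """One row per pattern A-P plus a class-totals block."""
    path = Path(path)
    pattern_rows = []
    for label in PATTERN_ORDER:
        p = PATTERNS[label]
        pattern_rows.append(
            {
                "pattern": label,
                "before_hpaii": p.before_lanes[0],
                "before_mspi": p.before_lanes[1],
                "after_hpaii": p.after_lanes[0],
                "after_mspi": p.after_lanes[1],
                "change_class": p.change_class,
                "count": summary.pattern_counts[label],
                "pct": round(100.0 * summary.pattern_counts[label] / summary.n_total, 2),
            }
        )
    class_rows = [
        {
            "change_class": c,
            "count": summary.class_counts[c],
            "pct": round(summary.class_percentages[c], 2),
        }
        for c in ("no_change", "demethylation", "methylation")
    ]
    if fmt == "json":
        _write_json(
            {
                "patterns": pattern_rows,
                "class_totals": class_rows,
                "n_total": summary.n_total,
                "n_inconsistent": summary.n_inconsistent,
            },
            path,
        )
        return
    with open(path, "w") as fh:
        pd.DataFrame(pattern_rows).to_csv(fh, index=False)
        fh.write("\n")
        pd.DataFrame(class_rows).to_csv(fh, index=False)


def write_recovery_report(
    summary: RecoverySummary, path: str | Path, fmt: str = "csv"
) -> None:
    """Recovery-class counts in the a..i, branch-total, total column layout."""
    path = Path(path)
    row = {label: summary.class_counts[label] for label in RECOVERY_CLASS_ORDER}
    row["a+b+c"] = summary.demethylation_branch_total
    row["d+e+f"] = summary.methylation_branch_total
    row["total"] = summary.n_total
    if fmt == "json":
        _write_json(row, path)
    else:
        cols = list("abc") + ["a+b+c"] + list("def") + ["d+e+f"] + list("ghi") + ["total"]
        pd.DataFrame([row])[cols].to_csv(path, index=False)


def write_bisulfite_report(
    summary: BisulfiteSummary, path: str | Path, fmt: str = "csv"
) -> None:
    path = Path(path)
    rows = [
        {
            "context": ctx,
            "n_methylated": summary.n_methylated[ctx],
            "n_total": summary.n_total[ctx],
            "pct_methylated": (
                round(summary.pct_methylated[ctx], 2)
                if ctx in summary.pct_methylated
                else ""
            ),
        }
        for ctx in ("CG", "CHG", "CHH")
    ]
    if fmt == "json":
        payload = {
            "contexts": rows,
            "n_excluded": summary.n_excluded,
            "overall_pct": (
                round(summary.overall_pct, 2) if summary.overall_pct is not None else None
            ),
        }
        _write_json(payload, path)
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
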