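"""Readers and writers for the plain-text formats the package exchanges.

Formats: fluctuation counts files (one integer per line with an optional
``# label, N_t, plating_fraction`` header), bit-exact pileup tables
(``pos ref nA nC nG nT``, tab-separated, 1-based), barcode manifests
(``well front back``), OD600 tables (``time_h od replicate``), minimal SAM
(M-only CIGARs; read back via pysam), FASTA/FASTQ via Biopython, and JSON
reports with stable key order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enrichment import BarcodeManifest
from .fluctuation import FluctuationExperiment
from .growth import GrowthCurve
from .spectrum import PileupMatrix

__all__ = [
    "read_counts_file",
    "write_counts_file",
    "read_pileup_table",
    "write_pileup_table",
    "read_barcode_manifest",
    "write_barcode_manifest",
    "read_od_table",
    "write_od_table",
    "write_sam",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_report",
]


def read_counts_file(path) -> FluctuationExperiment:
    """Read a fluctuation counts file: one mutant count per line, optional
    header ``# label, N_t, plating_fraction``."""
    label, n_final, z = "", None, 1.0
    counts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = [p.strip() for p in line[1:].split(",")]
            if len(parts) >= 2:
                label, n_final = parts[0], float(parts[1])
            if len(parts) >= 3:
                z = float(parts[2])
            continue
        counts.append(int(line))
    if n_final is None:
        raise ValueError(f"{path}: missing '# label, N_t[, plating_fraction]' header")
    if not counts:
        raise ValueError(f"{path}: no culture counts found")
    return FluctuationExperiment(
        counts=tuple(counts), n_final=n_final, plating_fraction=z, label=label
    )


def write_counts_file(path, experiment: FluctuationExperiment) -> None:
    lines = [
        f"# {experiment.label}, {experiment.n_final}, {experiment.plating_fraction}"
    ]
    lines += [str(c) for c in experiment.counts]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pileup_table(path) -> PileupMatrix:
    """Read the bit-exact pileup table: ``pos ref nA nC nG nT``."""
    df = pd.read_csv(path, sep="\t")
    expected = ["pos", "ref", "nA", "nC", "nG", "nT"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: header must be exactly {expected}")
    return PileupMatrix(
        positions=df["pos"].to_numpy(),
        ref="".join(df["ref"]),
        counts=df[["nA", "nC", "nG", "nT"]].to_numpy(),
    )


def write_pileup_table(path, pileup: PileupMatrix) -> None:
    df = pd.DataFrame(
        {
            "pos": pileup.positions,
            "ref": list(pileup.ref),
            "nA": pileup.counts[:, 0],
            "nC": pileup.counts[:, 1],
            "nG": pileup.counts[:, 2],
            "nT": pileup.counts[:, 3],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_barcode_manifest(path, max_mismatch: int = 1) -> BarcodeManifest:
    """Tab-separated ``well front back`` (header optional)."""
    wells = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("well\t"):
            continue
        well, front, back = line.split("\t")
        wells[well] = (front, back)
    return BarcodeManifest(wells=wells, max_mismatch=max_mismatch)


def write_barcode_manifest(path, manifest: BarcodeManifest) -> None:
    lines = ["well\tfront\tback"]
    lines += [f"{w}\t{f}\t{b}" for w, (f, b) in manifest.wells.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_od_table(path) -> list[GrowthCurve]:
    """Tab-separated ``time_h od replicate`` -> one GrowthCurve per replicate."""
    df = pd.read_csv(path, sep="\t")
    curves = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=tuple(grp["time_h"]),
                od=tuple(grp["od"]),
                replicate=str(rep),
            )
        )
    return curves


def write_od_table(path, curves: list[GrowthCurve]) -> None:
    rows = [
        {"time_h": t, "od": x, "replicate": c.replicate}
        for c in curves
        for t, x in zip(c.times, c.od)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sam(path, reads, reference_name: str, reference_length: int) -> None:
    """Write gapless reads as minimal SAM (M-only CIGARs, Phred+33 quals).

    ``reads``: iterable of ``(pos1, sequence, qualities)``.
    """
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{reference_name}\tLN:{reference_length}",
    ]
    for i, (pos1, seq, quals) in enumerate(
        sorted(reads, key=lambda r: r[0])
    ):
        qual_str = "".join(chr(q + 33) for q in quals)
        lines.append(
            f"read{i}\t0\t{reference_name}\t{pos1}\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual_str}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fastq(path):
    """FASTQ (Phred+33) -> list of Biopython SeqRecords."""
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(path, records) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> str:
    """First record of a FASTA file as an uppercase string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(path, report: dict) -> None:
    """Structured JSON report with stable key order (diff-able runs)."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n")
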