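"""Barcoded-amplicon enrichment calling for multi-well evolution campaigns.

Long amplicon reads carry a well-identifying barcode at each end.  The
pipeline here: (1) filter reads on mean quality, length and two-sided
barcode fidelity and assign each survivor to its well; (2) build per-well
per-position base distributions from gapless alignments, removing gap-only
("blank") columns; (3) call mutations significant when they reach a global
pooled-read frequency threshold OR appear in a minimum number of wells; and
(4) annotate coding effects against a CDS with the standard genetic code.

Positions are 1-based gene coordinates throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .spectrum import BASES, _BASE_INDEX

__all__ = [
    "BarcodeManifest",
    "AssignedRead",
    "WellMutationTable",
    "SignificantMutation",
    "filter_reads",
    "gapless_align",
    "well_distributions",
    "call_significant",
    "annotate_codon",
]

_GAP_INDEX = 4  # counts column for '-' in aligned sequences


@dataclass(frozen=True)
class BarcodeManifest:
    """Well label -> (front barcode, back barcode), plus match tolerance.

    Barcodes must be unique per end and of one length per end; matching is
    Hamming distance with at most ``max_mismatch`` mismatches, and a read
    whose best match is shared by two wells is discarded as ambiguous.
    """

    wells: dict[str, tuple[str, str]]
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        fronts = [fb for fb, _ in self.wells.values()]
        backs = [bb for _, bb in self.wells.values()]
        if not self.wells:
            raise ValueError("manifest must contain at least one well")
        if len(set(fronts)) != len(fronts) or len(set(backs)) != len(backs):
            raise ValueError("barcodes must be unique per end")
        if len({len(b) for b in fronts}) != 1 or len({len(b) for b in backs}) != 1:
            raise ValueError("all barcodes must share one length per end")

    @property
    def front_length(self) -> int:
        return len(next(iter(self.wells.values()))[0])

    @property
    def back_length(self) -> int:
        return len(next(iter(self.wells.values()))[1])


@dataclass(frozen=True)
class AssignedRead:
    well: str
    sequence: str  # insert only, barcodes stripped
    offset: int = 0  # 0-based gapless alignment offset into the gene


@dataclass
class WellMutationTable:
    """Per-well read counts and per-position base distributions.

    ``counts[well]`` is an (L, 5) array over A,C,G,T,'-'; ``blanks[well]``
    lists 1-based columns that were gap-only within the well and therefore
    removed from that well's distributions.  Wells that end up with zero
    surviving reads are kept (flagged) with empty tables.
    """

    reference: str
    counts: dict[str, np.ndarray]
    n_reads: dict[str, int]
    blanks: dict[str, list[int]] = field(default_factory=dict)

    @property
    def empty_wells(self) -> list[str]:
        return [w for w, n in self.n_reads.items() if n == 0]

    def frequencies(self, well: str) -> np.ma.MaskedArray:
        """Base distribution (A,C,G,T only) per position for one well;
        blank/uncovered positions masked.  Rows sum to 1 where covered."""
        c = self.counts[well][:, :4].astype(float)
        total = c.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = c / total[:, None]
        return np.ma.masked_invalid(f)


@dataclass(frozen=True)
class SignificantMutation:
    position: int  # 1-based gene coordinate
    ref: str
    alt: str
    global_frequency: float
    n_wells: int
    codon: int | None = None
    aa_change: str | None = None  # e.g. D54N, Q237*, or silent/noncoding tag
    effect: str | None = None  # missense | nonsense | silent | noncoding


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_barcode(
    observed: str, candidates: dict[str, str], max_mismatch: int
) -> tuple[str | None, str]:
    """Best unique well for an observed barcode.

    Returns ``(well, "ok")``, ``(None, "unmatched")`` when no barcode lies
    within ``max_mismatch``, or ``(None, "ambiguous")`` when two wells tie
    at the best (admissible) distance."""
    best, best_d, tied = None, max_mismatch + 1, False
    for well, bc in candidates.items():
        d = _hamming(observed, bc)
        if d < best_d:
            best, best_d, tied = well, d, False
        elif d == best_d and best is not None:
            tied = True
    if best is None:
        return None, "unmatched"
    if tied:
        return None, "ambiguous"
    return best, "ok"


def filter_reads(
    reads,
    manifest: BarcodeManifest,
    min_quality: float = 20.0,
    length_range: tuple[int, int] | None = None,
) -> tuple[list[AssignedRead], dict[str, int]]:
    """Quality/length/barcode filtering with well assignment.

    ``reads`` is an iterable of Biopython ``SeqRecord`` objects (e.g. from
    ``SeqIO.parse(path, "fastq")``) or of ``(sequence, qualities)`` tuples.
    A read survives iff its mean Phred quality is >= ``min_quality``, its
    length falls inside ``length_range`` (inclusive), and BOTH its front and
    back barcodes match a single well within the manifest's mismatch
    tolerance; the two ends must agree on the well.  Returns the surviving
    reads (barcodes stripped) and a dictionary of per-stage drop counts.
    """
    stats = {
        "total": 0,
        "low_quality": 0,
        "bad_length": 0,
        "unmatched_barcode": 0,
        "ambiguous_barcode": 0,
        "assigned": 0,
    }
    fronts = {w: fb for w, (fb, _) in manifest.wells.items()}
    backs = {w: bb for w, (_, bb) in manifest.wells.items()}
    flen, blen = manifest.front_length, manifest.back_length
    out: list[AssignedRead] = []
    for rec in reads:
        stats["total"] += 1
        if hasattr(rec, "seq"):
            seq = str(rec.seq)
            quals = rec.letter_annotations.get("phred_quality")
        else:
            seq, quals = rec
        if quals is not None and float(np.mean(quals)) < min_quality:
            stats["low_quality"] += 1
            continue
        if length_range is not None and not (
            length_range[0] <= len(seq) <= length_range[1]
        ):
            stats["bad_length"] += 1
            continue
        if len(seq) < flen + blen:
            stats["bad_length"] += 1
            continue
        w_front, f_status = _match_barcode(seq[:flen], fronts, manifest.max_mismatch)
        w_back, b_status = _match_barcode(seq[-blen:], backs, manifest.max_mismatch)
        if w_front is None or w_back is None:
            if "ambiguous" in (f_status, b_status):
                stats["ambiguous_barcode"] += 1
            else:
                stats["unmatched_barcode"] += 1
            continue
        if w_front != w_back:
            stats["ambiguous_barcode"] += 1
            continue
        out.append(AssignedRead(well=w_front, sequence=seq[flen : len(seq) - blen]))
        stats["assigned"] += 1
    return out, stats


def gapless_align(sequence: str, reference: str) -> tuple[int, int]:
    """Trivial gapless aligner: best 0-based offset of ``sequence`` within
    ``reference`` by minimum Hamming mismatches.  Returns (offset,
    n_mismatches).  Intended for synthetic amplicons; real campaigns supply
    external alignments."""
    L, n = len(sequence), len(reference)
    if L > n:
        raise ValueError("sequence longer than reference; gapless fit impossible")
    seq_arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    best_off, best_mm = 0, L + 1
    for off in range(n - L + 1):
        mm = int((seq_arr != ref_arr[off : off + L]).sum())
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    return best_off, best_mm


def well_distributions(
    assigned: list[AssignedRead],
    reference: str,
    align: bool = False,
) -> WellMutationTable:
    """Per-well, per-position base distributions from gapless alignments.

    Each read is placed at its ``offset`` (or aligned with
    :func:`gapless_align` when ``align=True``); bases, including ``-`` gap
    characters from externally aligned input, are tallied per well.
    Columns that are gap-only within a well are recorded as blanks and
    excluded from that well's distributions.
    """
    reference = reference.upper()
    L = len(reference)
    counts: dict[str, np.ndarray] = {}
    n_reads: dict[str, int] = {}
    for read in assigned:
        tbl = counts.setdefault(read.well, np.zeros((L, 5), dtype=np.int64))
        n_reads[read.well] = n_reads.get(read.well, 0) + 1
        off = gapless_align(read.sequence.replace("-", ""), reference)[0] \
            if align else read.offset
        for i, base in enumerate(read.sequence.upper()):
            pos = off + i
            if not 0 <= pos < L:
                continue
            if base in _BASE_INDEX:
                tbl[pos, _BASE_INDEX[base]] += 1
            elif base == "-":
                tbl[pos, _GAP_INDEX] += 1
    blanks = {}
    for well, tbl in counts.items():
        covered = tbl.sum(axis=1) > 0
        gap_only = covered & (tbl[:, :4].sum(axis=1) == 0)
        blanks[well] = (np.nonzero(gap_only)[0] + 1).tolist()
    return WellMutationTable(
        reference=reference, counts=counts, n_reads=n_reads, blanks=blanks
    )


def call_significant(
    table: WellMutationTable,
    f_global: float = 0.10,
    n_wells: int = 4,
    presence_floor: float = 0.10,
    cds: str | None = None,
    frame_offset: int = 0,
) -> list[SignificantMutation]:
    """Two-criterion significance calling over pooled wells.

    A (position, alt) pair is called significant iff its global frequency --
    pooled alt reads divided by pooled covering reads across all wells -- is
    at least ``f_global``, OR it is *present* (within-well frequency >=
    ``presence_floor``) in at least ``n_wells`` wells.  Output is sorted by
    global frequency, descending.  When ``cds`` is given, each call is
    annotated with its codon effect.
    """
    ref = table.reference
    L = len(ref)
    pooled = np.zeros((L, 4), dtype=np.int64)
    for tbl in table.counts.values():
        pooled += tbl[:, :4]
    total = pooled.sum(axis=1)
    calls: list[SignificantMutation] = []
    for pos0 in range(L):
        if total[pos0] == 0:
            continue
        ref_base = ref[pos0]
        for j, alt in enumerate(BASES):
            if alt == ref_base or pooled[pos0, j] == 0:
                continue
            gfreq = pooled[pos0, j] / total[pos0]
            wells_present = 0
            for tbl in table.counts.values():
                cov = tbl[pos0, :4].sum()
                if cov > 0 and tbl[pos0, j] / cov >= presence_floor:
                    wells_present += 1
            if gfreq >= f_global or wells_present >= n_wells:
                codon = aa_change = effect = None
                if cds is not None:
                    codon, aa_change, effect = annotate_codon(
                        pos0 + 1, alt, cds, frame_offset=frame_offset
                    )
                calls.append(
                    SignificantMutation(
                        position=pos0 + 1,
                        ref=ref_base,
                        alt=alt,
                        global_frequency=float(gfreq),
                        n_wells=wells_present,
                        codon=codon,
                        aa_change=aa_change,
                        effect=effect,
                    )
                )
    calls.sort(key=lambda c: -c.global_frequency)
    return calls


def annotate_codon(
    position: int,
    alt: str,
    cds: str,
    frame_offset: int = 0,
) -> tuple[int | None, str, str]:
    """Amino-acid effect of a single-base substitution in a CDS.

    ``position`` is 1-based in the supplied sequence; ``frame_offset`` bases
    are skipped before the reading frame starts.  Returns ``(codon_number,
    label, effect)`` where the label is e.g. ``D54N``, ``Q237*`` for a
    nonsense change, ``D54D`` for silent, and effect is one of
    ``missense``/``nonsense``/``silent``/``noncoding``.
    """
    cds = cds.upper()
    alt = alt.upper()
    if alt not in _BASE_INDEX:
        raise ValueError(f"alt must be one of {BASES}, got {alt!r}")
    idx = position - 1 - frame_offset
    coding_len = (len(cds) - frame_offset) // 3 * 3
    if idx < 0 or idx >= coding_len:
        return None, "noncoding", "noncoding"
    codon_number = idx // 3 + 1
    codon_start = frame_offset + (codon_number - 1) * 3
    codon = cds[codon_start : codon_start + 3]
    within = idx % 3
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    label = f"{aa_ref}{codon_number}{aa_alt}"
    if aa_alt == aa_ref:
        effect = "silent"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return codon_number, label, effect
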