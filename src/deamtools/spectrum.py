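"""Per-position mutation-spectrum profiling from targeted deep sequencing.

Quality-filtered, gaplessly aligned reads are tallied into a per-position
base-count pileup; per-base frequencies ``f_B,i = N_B,i / sum_B N_B,i`` are
then summarised with the windowed statistics used for targeted-deaminase
spectra: trimmed unweighted moving averages, windowed average substitutions
per base (s.p.b.), on/off-target fold enrichment with a coordinate offset
between strains, and background subtraction of sequencing-error frequencies
with renormalised per-type fractions.

All coordinates in this module are 1-based and windows are inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "SUBSTITUTION_TYPES",
    "PileupMatrix",
    "FrequencyProfile",
    "SmoothedProfile",
    "SubstitutionSummary",
    "build_pileup",
    "position_frequencies",
    "moving_average",
    "mean_spb",
    "fold_enrichment",
    "background_subtract",
    "detect_onset",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if a != r
)


def _parse_substitution(substitution: str) -> tuple[str, str]:
    try:
        ref, alt = substitution.split(">")
    except ValueError:
        raise ValueError(f"substitution must look like 'C>T', got {substitution!r}")
    if ref not in _BASE_INDEX or alt not in _BASE_INDEX or ref == alt:
        raise ValueError(f"invalid substitution type {substitution!r}")
    return ref, alt


@dataclass
class PileupMatrix:
    """Per-reference-position base counts after quality filtering.

    ``counts[i, j]`` is the number of reads whose (quality-passing) call at
    ``positions[i]`` is base ``BASES[j]``.  ``offset`` records any signed
    coordinate shift applied for cross-strain comparison.
    """

    positions: np.ndarray  # 1-based, strictly increasing
    ref: str
    counts: np.ndarray  # (n_positions, 4) ints, columns A,C,G,T
    qmin_applied: int | None = None
    offset: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.positions.size, 4):
            raise ValueError("counts must have shape (n_positions, 4)")
        if len(self.ref) != self.positions.size:
            raise ValueError("ref must give one base per position")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        bad = set(self.ref) - set(BASES)
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {bad}")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class FrequencyProfile:
    """Per-position, per-base frequencies on the reference strand.

    ``freqs`` is a masked (n_positions, 4) array; zero-coverage positions
    are masked rather than zero-filled so windowed means never deflate.
    """

    positions: np.ndarray
    ref: str
    freqs: np.ma.MaskedArray
    coverage: np.ndarray
    offset: int = 0

    def substitution_frequency(self, substitution: str) -> np.ma.MaskedArray:
        """Frequency of ``alt`` calls at positions whose reference base is
        ``ref``; other positions masked."""
        ref, alt = _parse_substitution(substitution)
        vals = self.freqs[:, _BASE_INDEX[alt]].copy()
        ref_arr = np.frombuffer(self.ref.encode(), dtype="S1").astype("U1")
        vals[ref_arr != ref] = np.ma.masked
        return vals

    def shifted(self, offset: int) -> "FrequencyProfile":
        """Return a copy with ``offset`` added to every position (used to
        line a control strain up with a target strain whose locus carries
        an insertion)."""
        return FrequencyProfile(
            positions=self.positions + offset,
            ref=self.ref,
            freqs=self.freqs,
            coverage=self.coverage,
            offset=self.offset + offset,
        )


@dataclass
class SmoothedProfile:
    """Trimmed moving-average trend of a per-position profile."""

    positions: np.ndarray
    trend: np.ma.MaskedArray
    half_width: int
    sigma: float
    n_excluded: np.ndarray  # outliers dropped from each window


@dataclass
class SubstitutionSummary:
    """Windowed per-substitution-type statistics.

    Produced by :func:`fold_enrichment` (mean s.p.b. per type in target and
    control, their ratio, replicate SD) and :func:`background_subtract`
    (error-corrected mean s.p.b. and renormalised fractions).  Undefined
    entries are NaN.
    """

    window: tuple[int, int]
    offset: int
    target_spb: dict[str, float]
    control_spb: dict[str, float]
    fold: dict[str, float] = field(default_factory=dict)
    replicate_sd: dict[str, float] = field(default_factory=dict)
    corrected: dict[str, float] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)


def _iter_reads(reads, reference: str):
    """Yield (pos1, seq, quals) from a SAM file/path (via pysam) or an
    iterable of (pos1, seq, quals) tuples."""
    if isinstance(reads, (str,)) or hasattr(reads, "read"):
        import pysam

        with pysam.AlignmentFile(str(reads), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped:
                    continue
                ops = {op for op, _ in (aln.cigartuples or [])}
                if ops - {0}:  # anything beyond M is rejected
                    yield None
                    continue
                quals = aln.query_qualities
                yield (
                    aln.reference_start + 1,
                    aln.query_sequence,
                    list(quals) if quals is not None else [93] * len(aln.query_sequence),
                )
    else:
        yield from reads


def build_pileup(
    reads,
    reference,
    qmin: int = 35,
) -> PileupMatrix:
    """Tally quality-passing base calls into a per-position pileup.

    Parameters
    ----------
    reads
        A SAM path/handle (gapless alignments, M-only CIGARs) or an iterable
        of ``(position, sequence, qualities)`` tuples with 1-based positions
        and numeric Phred qualities.
    reference
        Reference sequence (str or Biopython SeqRecord).
    qmin
        Base calls with Phred quality strictly below this are dropped.

    Reads overhanging the reference are trimmed (with a summary warning);
    alignments containing indels are rejected per read.
    """
    ref_seq = str(getattr(reference, "seq", reference)).upper()
    n = len(ref_seq)
    counts = np.zeros((n, 4), dtype=np.int64)
    n_trimmed = n_rejected = 0
    for item in _iter_reads(reads, ref_seq):
        if item is None:
            n_rejected += 1
            continue
        pos1, seq, quals = item
        start = pos1 - 1
        if start < 0 or start + len(seq) > n:
            n_trimmed += 1
        base_idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        # map ASCII A/C/G/T to 0..3, everything else (incl. N) to 4
        lut = np.full(256, 4, dtype=np.int8)
        for b, j in _BASE_INDEX.items():
            lut[ord(b)] = j
        codes = lut[base_idx]
        ref_pos = start + np.arange(len(seq))
        keep = (
            (codes < 4)
            & (np.asarray(quals) >= qmin)
            & (ref_pos >= 0)
            & (ref_pos < n)
        )
        np.add.at(counts, (ref_pos[keep], codes[keep]), 1)
    if n_trimmed:
        warnings.warn(f"{n_trimmed} read(s) overhung the reference and were trimmed")
    if n_rejected:
        warnings.warn(f"{n_rejected} indel-containing alignment(s) rejected")
    return PileupMatrix(
        positions=np.arange(1, n + 1),
        ref=ref_seq,
        counts=counts,
        qmin_applied=qmin,
    )


def position_frequencies(
    pileup: PileupMatrix, pseudocount: bool = False
) -> FrequencyProfile:
    """Per-base frequencies ``f_B,i = N_B,i / (N_A,i+N_C,i+N_G,i+N_T,i)``.

    Positions with zero total coverage are masked, never zero-filled.
    ``pseudocount=True`` adds one count to every base at every position
    first (for finite fold-enrichment ratios; off by default).
    """
    counts = pileup.counts + (1 if pseudocount else 0)
    total = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = counts / total[:, None]
    freqs = np.ma.masked_invalid(freqs)
    return FrequencyProfile(
        positions=pileup.positions.copy(),
        ref=pileup.ref,
        freqs=freqs,
        coverage=total,
        offset=pileup.offset,
    )


def moving_average(
    values,
    w: int = 10,
    k: float = 3.0,
    positions: np.ndarray | None = None,
    global_sd: bool = False,
    min_members: int = 3,
) -> SmoothedProfile:
    """Unweighted moving average with single-pass k-sigma outlier exclusion.

    For each position the up-to-``2w+1`` neighbouring values are gathered
    (windows shrink at the edges), values further than ``k`` standard
    deviations from the window mean are dropped in a single pass, and the
    plain mean of the survivors is returned.  Windows left with fewer than
    ``min_members`` values are masked.  ``global_sd=True`` uses the
    profile-wide SD for the exclusion threshold instead of the window SD.
    """
    if w < 1:
        raise ValueError("window half-width w must be >= 1")
    if k <= 0:
        raise ValueError("outlier threshold k must be positive")
    vals = np.ma.masked_invalid(np.ma.asarray(values, dtype=float))
    n = vals.size
    if positions is None:
        positions = np.arange(1, n + 1)
    trend = np.ma.masked_all(n, dtype=float)
    n_excluded = np.zeros(n, dtype=np.int64)
    g_sd = float(vals.std()) if global_sd else None
    for i in range(n):
        window = vals[max(0, i - w) : min(n, i + w + 1)]
        members = window.compressed()
        if members.size == 0:
            continue
        mean = members.mean()
        sd = g_sd if global_sd else members.std()
        if sd > 0:
            keep = np.abs(members - mean) <= k * sd
        else:
            keep = np.ones(members.size, dtype=bool)
        survivors = members[keep]
        n_excluded[i] = members.size - survivors.size
        if survivors.size >= min_members:
            trend[i] = survivors.mean()
    return SmoothedProfile(
        positions=np.asarray(positions),
        trend=trend,
        half_width=w,
        sigma=k,
        n_excluded=n_excluded,
    )


def _window_slice(profile: FrequencyProfile, window: tuple[int, int]) -> np.ndarray:
    start, end = window
    if start > end:
        raise ValueError("window start must not exceed end")
    return (profile.positions >= start) & (profile.positions <= end)


def mean_spb(
    profile: FrequencyProfile,
    window: tuple[int, int],
    substitution: str,
) -> float:
    """Average substitutions per base for one type over an inclusive window.

    The mean of ``f_alt,i`` over window positions whose reference base
    matches the substitution's reference; non-matching and zero-coverage
    positions are excluded from numerator and denominator alike.  NaN when
    no matching position exists.
    """
    sub = profile.substitution_frequency(substitution)
    sel = sub[_window_slice(profile, window)].compressed()
    if sel.size == 0:
        return math.nan
    return float(sel.mean())


def fold_enrichment(
    target: FrequencyProfile,
    control: FrequencyProfile,
    window: tuple[int, int],
    offset: int = 23,
    substitutions=SUBSTITUTION_TYPES,
    replicates=None,
) -> SubstitutionSummary:
    """Per-substitution-type on/off-target fold enrichment over a window.

    The control profile is shifted by ``offset`` positions before windowing,
    compensating for an insertion present only in the targeted strain (the
    promoter landing site); the same 1-based inclusive ``window`` then
    addresses homologous bases in both strains.  Each type's enrichment is
    ``mean_spb(target) / mean_spb(control)``; a zero control mean gives NaN
    (enable the pseudocount in :func:`position_frequencies` for finite
    ratios).  ``replicates`` may be a sequence of ``(target, control)``
    profile pairs from biological replicates; the SD of their per-type
    ratios is reported.
    """
    ctrl = control.shifted(offset) if offset else control
    target_spb, control_spb, fold = {}, {}, {}
    for sub in substitutions:
        t = mean_spb(target, window, sub)
        c = mean_spb(ctrl, window, sub)
        target_spb[sub], control_spb[sub] = t, c
        fold[sub] = t / c if c and c > 0 else math.nan
    replicate_sd = {}
    if replicates:
        per_type = {sub: [] for sub in substitutions}
        for t_prof, c_prof in replicates:
            c_shift = c_prof.shifted(offset) if offset else c_prof
            for sub in substitutions:
                t = mean_spb(t_prof, window, sub)
                c = mean_spb(c_shift, window, sub)
                per_type[sub].append(t / c if c and c > 0 else math.nan)
        replicate_sd = {
            sub: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
            for sub, v in per_type.items()
        }
    return SubstitutionSummary(
        window=tuple(window),
        offset=offset,
        target_spb=target_spb,
        control_spb=control_spb,
        fold=fold,
        replicate_sd=replicate_sd,
    )


def background_subtract(
    target: FrequencyProfile,
    control: FrequencyProfile,
    window: tuple[int, int],
    offset: int = 0,
    substitutions=SUBSTITUTION_TYPES,
) -> SubstitutionSummary:
    """Background-corrected per-type s.p.b. and substitution fractions.

    For each type the control (sequencing-error) mean s.p.b. is subtracted
    from the target's, clipping at zero; the corrected values are then
    renormalised to the fraction of substitutions occurring at each type.
    Fractions are NaN when every corrected value is zero.
    """
    ctrl = control.shifted(offset) if offset else control
    target_spb, control_spb, corrected = {}, {}, {}
    for sub in substitutions:
        t = mean_spb(target, window, sub)
        c = mean_spb(ctrl, window, sub)
        target_spb[sub], control_spb[sub] = t, c
        t = 0.0 if math.isnan(t) else t
        c = 0.0 if math.isnan(c) else c
        corrected[sub] = max(0.0, t - c)
    total = sum(corrected.values())
    if total > 0:
        fractions = {sub: v / total for sub, v in corrected.items()}
    else:
        fractions = {sub: math.nan for sub in corrected}
    return SubstitutionSummary(
        window=tuple(window),
        offset=offset,
        target_spb=target_spb,
        control_spb=control_spb,
        corrected=corrected,
        fractions=fractions,
    )


def detect_onset(
    target: FrequencyProfile,
    control: FrequencyProfile,
    tss: int,
    plateau_window: tuple[int, int],
    substitution: str = "C>T",
    offset: int = 0,
    threshold: float = 0.5,
) -> int:
    """First position downstream of a transcription start site where the
    background-corrected substitution frequency reaches ``threshold`` times
    the plateau level.

    The plateau level is the background-subtracted mean s.p.b. of
    ``substitution`` over ``plateau_window``.  Scanning proceeds downstream
    from ``tss + 1`` over positions whose reference base matches; returns
    the 1-based position of the first crossing.  Raises ``ValueError`` if
    no crossing exists (no detectable mutagenesis onset).
    """
    ctrl = control.shifted(offset) if offset else control
    plateau = background_subtract(
        target, ctrl, plateau_window, substitutions=(substitution,)
    ).corrected[substitution]
    if not plateau > 0:
        raise ValueError("no plateau signal; onset undefined")
    t_sub = target.substitution_frequency(substitution)
    c_sub = ctrl.substitution_frequency(substitution)
    c_by_pos = dict(zip(ctrl.positions.tolist(), c_sub))
    for idx in np.nonzero(target.positions > tss)[0]:
        t_val = t_sub[idx]
        if t_val is np.ma.masked:
            continue
        c_val = c_by_pos.get(int(target.positions[idx]), 0.0)
        if c_val is np.ma.masked or (isinstance(c_val, float) and math.isnan(c_val)):
            c_val = 0.0
        if float(t_val) - float(c_val) >= threshold * plateau:
            return int(target.positions[idx])
    raise ValueError("no onset crossing found downstream of the TSS")
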