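"""Seeded synthetic-data generators with ground-truth bookkeeping.

Every input the analysis modules consume can be generated here with known
truth: Luria-Delbrück-distributed fluctuation-assay colony counts (with
jackpots), positional substitution-frequency pileups emulating targeted
deaminase mutagenesis (a C>T plateau starting 9-12 nt downstream of a
promoter's transcription start, a distance-decaying G>A component, minority
A>G / T>C components, uniform sequencing error, and a two-point Phred
quality mixture), multi-well barcoded amplicon campaigns in which one
driver substitution sweeps most wells, and noisy exponential OD600 curves.

All generators take an integer seed (or an ``numpy.random.Generator``) and
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .enrichment import AssignedRead, BarcodeManifest
from .fluctuation import FluctuationExperiment
from .growth import GrowthCurve
from .spectrum import BASES, _BASE_INDEX, PileupMatrix

__all__ = [
    "FluctuationSimConfig",
    "MutagenesisProfileConfig",
    "sample_ld_counts",
    "simulate_fluctuation",
    "simulate_pileup",
    "simulate_pileup_pair",
    "simulate_reads",
    "random_barcode_manifest",
    "simulate_amplicon_campaign",
    "simulate_growth",
]

_MUTAGENIC_ALT = {"C": "T", "G": "A", "A": "G", "T": "C"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Fluctuation assays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluctuationSimConfig:
    """True per-division mutation rate plus culture growth/plating setup.

    ``mu`` is the chance a cell division produces a scorable mutant;
    cultures grow from ``n_initial`` to ``n_final`` cells, so the expected
    number of mutational events per culture is ``m = mu * (n_final -
    n_initial)``.  ``plating_fraction`` thins each culture's mutant count
    binomially before it is scored.
    """

    mu: float
    n_final: float
    n_initial: float = 1000.0
    n_cultures: int = 8
    plating_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if not self.n_final >= self.n_initial >= 1:
            raise ValueError("need n_final >= n_initial >= 1")
        if not 0 < self.plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")

    @property
    def m_true(self) -> float:
        return self.mu * (self.n_final - self.n_initial)


def sample_ld_counts(
    m: float,
    n_cultures: int,
    rng,
    clone_cap: float = 1e12,
) -> np.ndarray:
    """Draw per-culture mutant counts from the Luria-Delbrück distribution.

    Mutational events per culture are Poisson(``m``); each event arises at
    a time uniform with respect to population growth, so its clone's final
    size is ``floor(1/U)`` (the law ``q_j = 1/(j(j+1))``), capped at
    ``clone_cap``.  This compound Poisson matches the MSS recursion
    exactly.
    """
    rng = _rng(rng)
    k = rng.poisson(m, size=n_cultures)
    total = int(k.sum())
    if total == 0:
        return np.zeros(n_cultures, dtype=np.int64)
    sizes = np.floor(1.0 / rng.random(total))
    sizes = np.minimum(sizes, clone_cap)
    owner = np.repeat(np.arange(n_cultures), k)
    counts = np.zeros(n_cultures, dtype=float)
    np.add.at(counts, owner, sizes)
    return np.minimum(counts, np.iinfo(np.int64).max).astype(np.int64)


def simulate_fluctuation(
    config: FluctuationSimConfig,
    rng=None,
    synchronous: bool = False,
) -> tuple[FluctuationExperiment, dict]:
    """Simulate one fluctuation assay; returns (experiment, truth record).

    Default model (asynchronous): mutations strike at growth-uniform random
    times, clone sizes follow ``floor(1/U)``, reproducing the MSS
    Luria-Delbrück distribution exactly.  ``synchronous=True`` instead uses
    idealised synchronous doubling (clone sizes are exact powers of two:
    over ``g = log2(N_t/N_0)`` doublings, generation ``k`` contributes
    Poisson(``mu * N_0 * 2^(k-1)``) mutations each founding a clone of
    ``2^(g-k)`` cells); note its count distribution deviates measurably
    from the MSS pmf.
    """
    rng = _rng(config.seed if rng is None else rng)
    if synchronous:
        g = max(1, round(math.log2(config.n_final / config.n_initial)))
        counts = np.zeros(config.n_cultures, dtype=np.int64)
        for k in range(1, g + 1):
            new_cells = config.n_initial * 2 ** (k - 1)
            muts = rng.poisson(config.mu * new_cells, size=config.n_cultures)
            counts += muts * 2 ** (g - k)
    else:
        counts = sample_ld_counts(
            config.m_true, config.n_cultures, rng, clone_cap=config.n_final
        )
    z = config.plating_fraction
    if z < 1.0:
        counts = rng.binomial(counts, z)
    experiment = FluctuationExperiment(
        counts=tuple(int(c) for c in counts),
        n_final=config.n_final,
        plating_fraction=z,
        label="simulated",
    )
    truth = {
        "mu": config.mu,
        "m": config.m_true,
        "n_final": config.n_final,
        "model": "synchronous" if synchronous else "asynchronous",
    }
    return experiment, truth


# ---------------------------------------------------------------------------
# Targeted mutagenesis pileups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutagenesisProfileConfig:
    """Stated world for positional mutagenesis profiles.

    A promoter at ``tss`` recruits the mutator; targeted substitution rates
    switch on at an onset drawn uniformly from ``onset_range`` nt downstream
    of the TSS.  Defaults: a C>T plateau of 1e-3 s.p.b. with minority A>G
    and T>C components of 1e-4, a G>A component starting at 5e-4 that
    decays exponentially with distance (length constant ``ga_decay_length``),
    uniform sequencing error, and a two-point Phred quality mixture with a
    fraction of calls below the quality filter.
    """

    length: int = 1200
    sequence: str | None = None
    gc_content: float = 0.40
    tss: int = 100
    onset_range: tuple[int, int] = (9, 12)
    plateau_rates: dict = field(
        default_factory=lambda: {"C>T": 1e-3, "A>G": 1e-4, "T>C": 1e-4}
    )
    ga_rate: float = 5e-4
    ga_decay_length: float = 300.0
    error_rate: float = 1e-4
    q_below_fraction: float = 0.10
    q_high: int = 40
    q_low: int = 30
    coverage: int = 100_000
    #: the profile's first increase occurs at a cytosine, so when the
    #: reference is randomly drawn the onset position is forced to C
    ensure_onset_cytosine: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, r in {**self.plateau_rates,
                        "G>A": self.ga_rate, "error": self.error_rate}.items():
            if not 0 <= r <= 1:
                raise ValueError(f"rate {name} must be in [0, 1]")
        if not 0 <= self.q_below_fraction < 1:
            raise ValueError("q_below_fraction must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length must equal `length`")
        if not 0 < self.tss <= self.length:
            raise ValueError("tss must lie within the reference")
        lo, hi = self.onset_range
        if not (0 <= lo <= hi and self.tss + hi <= self.length):
            raise ValueError("onset range must fit within the reference")


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A,C,G,T
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def substitution_rate_profile(
    config: MutagenesisProfileConfig, sequence: str, onset_pos: int
) -> np.ndarray:
    """True per-position targeted substitution probability (toward each
    position's mutagenic alt); zero upstream of ``onset_pos`` (1-based)."""
    rates = np.zeros(config.length)
    for i, base in enumerate(sequence):
        pos = i + 1
        if pos < onset_pos:
            continue
        if base == "G":
            rates[i] = config.ga_rate * math.exp(
                -(pos - onset_pos) / config.ga_decay_length
            )
        else:
            alt = _MUTAGENIC_ALT[base]
            rates[i] = config.plateau_rates.get(f"{base}>{alt}", 0.0)
    return rates


def simulate_pileup(
    config: MutagenesisProfileConfig,
    rng=None,
    mutagenesis: bool = True,
) -> tuple[PileupMatrix, dict]:
    """Counts-level pileup simulation; returns (pileup, truth).

    Per position, each of ``coverage`` reads first draws a true base (the
    targeted substitution with the position's profile rate, else the
    reference), then passes the uniform sequencing-error channel (misread
    to one of the other three bases with probability ``error_rate``), then
    survives the quality filter with probability ``1 - q_below_fraction``.
    The truth record stores the pre-error substitution counts per position.
    ``mutagenesis=False`` zeroes the targeted rates (an off-target /
    error-only control).
    """
    rng = _rng(config.seed if rng is None else rng)
    seq = config.sequence or _random_sequence(config.length, config.gc_content, rng)
    lo, hi = config.onset_range
    onset_offset = int(rng.integers(lo, hi + 1))
    onset_pos = config.tss + onset_offset
    if config.sequence is None and config.ensure_onset_cytosine and mutagenesis:
        seq = seq[: onset_pos - 1] + "C" + seq[onset_pos:]
    profile = (
        substitution_rate_profile(config, seq, onset_pos)
        if mutagenesis
        else np.zeros(config.length)
    )
    n = config.coverage
    counts = np.zeros((config.length, 4), dtype=np.int64)
    true_sub_counts = np.zeros(config.length, dtype=np.int64)
    e = config.error_rate
    keep_p = 1.0 - config.q_below_fraction
    for i, base in enumerate(seq):
        ref_j = _BASE_INDEX[base]
        alt_j = _BASE_INDEX[_MUTAGENIC_ALT[base]]
        k_mut = rng.binomial(n, profile[i]) if profile[i] > 0 else 0
        true_sub_counts[i] = k_mut
        true_counts = np.zeros(4, dtype=np.int64)
        true_counts[ref_j] = n - k_mut
        true_counts[alt_j] += k_mut
        final = np.zeros(4, dtype=np.int64)
        for j in range(4):
            c = true_counts[j]
            if c == 0:
                continue
            if e > 0:
                errs = rng.binomial(c, e)
                final[j] += c - errs
                if errs:
                    others = [x for x in range(4) if x != j]
                    spread = rng.multinomial(errs, [1 / 3] * 3)
                    for o, s in zip(others, spread):
                        final[o] += s
            else:
                final[j] += c
        if keep_p < 1.0:
            final = rng.binomial(final, keep_p)
        counts[i] = final
    pileup = PileupMatrix(
        positions=np.arange(1, config.length + 1),
        ref=seq,
        counts=counts,
        qmin_applied=None,
    )
    truth = {
        "sequence": seq,
        "onset_offset": onset_offset,
        "onset_position": onset_pos,
        "tss": config.tss,
        "rate_profile": profile,
        "true_substitution_counts": true_sub_counts,
        "mutagenesis": mutagenesis,
    }
    return pileup, truth


def simulate_pileup_pair(
    config: MutagenesisProfileConfig,
    rng=None,
    insertion_length: int = 23,
) -> tuple[PileupMatrix, PileupMatrix, dict]:
    """Matched target / control pileups for on:off-target comparisons.

    The target strain carries the promoter plus a ``insertion_length``-bp
    landing-site insertion immediately upstream of the TSS; the control
    lacks it, so a control position maps to ``target position -
    insertion_length`` downstream of the insertion.  The control sees no
    mutagenesis, only sequencing error.  Returns (target, control, truth);
    pass ``offset=insertion_length`` when comparing the two.
    """
    rng = _rng(config.seed if rng is None else rng)
    target, truth = simulate_pileup(config, rng=rng)
    seq = truth["sequence"]
    ins_start = config.tss - insertion_length  # 0-based slice start
    if ins_start < 0:
        raise ValueError("tss must leave room for the insertion upstream")
    ctrl_seq = seq[:ins_start] + seq[config.tss:]
    ctrl_config = MutagenesisProfileConfig(
        length=len(ctrl_seq),
        sequence=ctrl_seq,
        tss=max(1, ins_start),
        onset_range=(0, 0),
        plateau_rates=config.plateau_rates,
        ga_rate=config.ga_rate,
        error_rate=config.error_rate,
        q_below_fraction=config.q_below_fraction,
        coverage=config.coverage,
    )
    control, _ = simulate_pileup(ctrl_config, rng=rng, mutagenesis=False)
    truth = {**truth, "insertion_length": insertion_length}
    return target, control, truth


def simulate_reads(
    config: MutagenesisProfileConfig,
    rng=None,
    qmin: int = 35,
) -> tuple[list[tuple[int, str, list[int]]], PileupMatrix, dict]:
    """Read-level simulation for exercising the pileup builder.

    Emits full-length gapless reads at position 1 with a two-point quality
    mixture (``q_high`` >= the filter, ``q_low`` below it).  Also returns
    the expected pileup counting only calls with quality >= ``qmin`` --
    with ``error_rate = 0`` and ``q_below_fraction = 0`` this equals the
    generator's substitution bookkeeping exactly.
    """
    rng = _rng(config.seed if rng is None else rng)
    seq = config.sequence or _random_sequence(config.length, config.gc_content, rng)
    lo, hi = config.onset_range
    onset_pos = config.tss + int(rng.integers(lo, hi + 1))
    if config.sequence is None and config.ensure_onset_cytosine:
        seq = seq[: onset_pos - 1] + "C" + seq[onset_pos:]
    profile = substitution_rate_profile(config, seq, onset_pos)
    L, n = config.length, config.coverage
    expected = np.zeros((L, 4), dtype=np.int64)
    reads = []
    base_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, j in _BASE_INDEX.items():
        lut[ord(b)] = j
    ref_codes = lut[base_arr]
    alt_codes = lut[[ord(_MUTAGENIC_ALT[b]) for b in seq]]
    for _ in range(n):
        mutate = rng.random(L) < profile
        codes = np.where(mutate, alt_codes, ref_codes)
        if config.error_rate > 0:
            err = rng.random(L) < config.error_rate
            shift = rng.integers(1, 4, size=L)
            codes = np.where(err, (codes + shift) % 4, codes)
        low_q = rng.random(L) < config.q_below_fraction
        quals = np.where(low_q, config.q_low, config.q_high)
        counted = quals >= qmin
        np.add.at(expected, (np.arange(L)[counted], codes[counted]), 1)
        read_seq = "".join(BASES[c] for c in codes)
        reads.append((1, read_seq, quals.tolist()))
    expected_pileup = PileupMatrix(
        positions=np.arange(1, L + 1), ref=seq, counts=expected, qmin_applied=qmin
    )
    truth = {"sequence": seq, "onset_position": onset_pos, "rate_profile": profile}
    return reads, expected_pileup, truth


# ---------------------------------------------------------------------------
# Barcoded amplicon campaigns
# ---------------------------------------------------------------------------


def random_barcode_manifest(
    n_wells: int,
    rng,
    barcode_length: int = 8,
    min_distance: int = 3,
    max_mismatch: int = 1,
) -> BarcodeManifest:
    """Random well barcodes with a minimum pairwise Hamming distance (so
    single-mismatch demultiplexing stays unambiguous)."""
    rng = _rng(rng)

    def draw_set() -> list[str]:
        chosen: list[str] = []
        while len(chosen) < n_wells:
            bc = "".join(rng.choice(list(BASES), size=barcode_length))
            if all(
                sum(x != y for x, y in zip(bc, other)) >= min_distance
                for other in chosen
            ):
                chosen.append(bc)
        return chosen

    fronts, backs = draw_set(), draw_set()
    wells = {
        f"well{str(i + 1).zfill(3)}": (fronts[i], backs[i]) for i in range(n_wells)
    }
    return BarcodeManifest(wells=wells, max_mismatch=max_mismatch)


def simulate_amplicon_campaign(
    n_wells: int = 177,
    reads_per_well: int = 40,
    gene: str | None = None,
    gene_length: int = 750,
    driver: tuple[int, str, float, float] = (160, "A", 0.85, 0.90),
    noise: tuple[int, int, float] = (10, 2, 0.05),
    manifest: BarcodeManifest | None = None,
    quality: int = 30,
    seed=None,
) -> tuple[list, BarcodeManifest, str, dict]:
    """Multi-well amplicon campaign in which one driver mutation sweeps.

    ``driver = (position, alt, well_fraction, within_well_freq)``: the
    driver substitution is planted in ``well_fraction`` of the wells, where
    it appears in ``within_well_freq`` of that well's reads.  ``noise =
    (n_mutations, wells_each, within_well_freq)`` scatters low-level
    passenger mutations, each confined to at most ``wells_each`` wells.
    Returns ``(records, manifest, gene, truth)`` where records are
    Biopython ``SeqRecord`` FASTQ-ready reads (front barcode + gene copy +
    back barcode, constant ``quality``).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = _rng(seed)
    if gene is None:
        gene = "ATG" + _random_sequence(gene_length - 3, 0.4, rng)
    L = len(gene)
    if manifest is None:
        manifest = random_barcode_manifest(n_wells, rng)
    well_names = list(manifest.wells)
    if len(well_names) < n_wells:
        raise ValueError("manifest has fewer wells than requested")
    well_names = well_names[:n_wells]

    d_pos, d_alt, d_frac, d_within = driver
    if not 1 <= d_pos <= L:
        raise ValueError("driver position outside the gene")
    if gene[d_pos - 1] == d_alt:
        raise ValueError("driver alt equals the reference base")
    n_driver_wells = int(round(d_frac * n_wells))
    driver_wells = set(rng.choice(well_names, size=n_driver_wells, replace=False))

    n_noise, wells_each, noise_within = noise
    noise_plan: list[tuple[int, str, set]] = []
    for _ in range(n_noise):
        while True:
            pos = int(rng.integers(1, L + 1))
            ref_b = gene[pos - 1]
            alt_b = str(rng.choice([b for b in BASES if b != ref_b]))
            if pos != d_pos:
                break
        chosen = set(rng.choice(well_names, size=wells_each, replace=False))
        noise_plan.append((pos, alt_b, chosen))

    records = []
    per_well_truth: dict[str, list[tuple[int, str]]] = {w: [] for w in well_names}
    read_id = 0
    for well in well_names:
        fb, bb = manifest.wells[well]
        muts_here = [(d_pos, d_alt, d_within)] if well in driver_wells else []
        for pos, alt_b, chosen in noise_plan:
            if well in chosen:
                muts_here.append((pos, alt_b, noise_within))
        per_well_truth[well] = [(p, a) for p, a, _ in muts_here]
        for _ in range(reads_per_well):
            copy = list(gene)
            for pos, alt_b, freq in muts_here:
                if rng.random() < freq:
                    copy[pos - 1] = alt_b
            read_seq = fb + "".join(copy) + bb
            rec = SeqRecord(
                Seq(read_seq),
                id=f"read{read_id}",
                description=well,
                letter_annotations={"phred_quality": [quality] * len(read_seq)},
            )
            records.append(rec)
            read_id += 1
    truth = {
        "gene": gene,
        "driver": {
            "position": d_pos,
            "ref": gene[d_pos - 1],
            "alt": d_alt,
            "wells": sorted(driver_wells),
            "within_well_freq": d_within,
        },
        "noise": [
            {"position": p, "alt": a, "wells": sorted(w)} for p, a, w in noise_plan
        ],
        "per_well": per_well_truth,
        "reads_per_well": reads_per_well,
    }
    return records, manifest, gene, truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def simulate_growth(
    rate: float = 0.2,
    od0: float = 0.05,
    times: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
    noise_sigma: float = 0.02,
    n_replicates: int = 3,
    seed=None,
) -> tuple[list[GrowthCurve], dict]:
    """Exponential OD600 curves with multiplicative lognormal noise."""
    rng = _rng(seed)
    curves = []
    for r in range(n_replicates):
        od = od0 * np.exp(rate * np.asarray(times))
        if noise_sigma > 0:
            od = od * np.exp(rng.normal(0.0, noise_sigma, size=len(times)))
        curves.append(GrowthCurve(times=tuple(times), od=tuple(od), replicate=f"rep{r+1}"))
    return curves, {"rate": rate, "od0": od0, "noise_sigma": noise_sigma}
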