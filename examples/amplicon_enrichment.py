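"""Call significant mutations in a multi-well amplicon campaign.

Simulates a drug-resistance evolution endpoint: barcoded long reads from
60 wells, one driver substitution swept into 85% of wells, plus scattered
low-level passenger mutations.  Demultiplexes, builds per-well base
distributions, and applies the two-criterion significance rule (>=10%
global frequency OR present in >=4 wells).
"""

from deamtools.enrichment import call_significant, filter_reads, well_distributions
from deamtools.simulate import simulate_amplicon_campaign

records, manifest, gene, truth = simulate_amplicon_campaign(
    n_wells=60,
    reads_per_well=20,
    gene_length=300,
    driver=(40, "A", 0.85, 0.90),  # position 40, G>A-style, 85% of wells
    noise=(8, 2, 0.04),            # 8 passengers, <=2 wells each, 4% within well
    seed=11,
)

assigned, stats = filter_reads(records, manifest, min_quality=20)
print(f"reads: {stats['total']} total, {stats['assigned']} assigned to wells")

table = well_distributions(assigned, gene)
calls = call_significant(table, f_global=0.10, n_wells=4, cds=gene)

print(f"significant calls: {len(calls)}")
for c in calls:
    print(
        f"  pos {c.position} {c.ref}>{c.alt}: global frequency "
        f"{c.global_frequency:.1%}, present in {c.n_wells} wells, "
        f"codon {c.codon} ({c.aa_change}, {c.effect})"
    )
d = truth["driver"]
print(f"truth: driver at pos {d['position']} {d['ref']}>{d['alt']} "
      f"in {len(d['wells'])} wells -- passengers stay below both thresholds")
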