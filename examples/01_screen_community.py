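"""Recover planted prophage contigs from a synthetic metagenome.

Builds a three-genus community (one chromosome per genus with an embedded
prophage drawn from the same compositional model), screens all >= 10 kb
contigs against one driver phage genome per genus at the 0.6 correlation
threshold, and bins the recovered contigs from their ORF annotations.
"""

from pgsr.screening import DriverSet, bin_contig, screen_contigs
from pgsr import simulate as sim

community = sim.make_community(seed=3)
drivers = DriverSet.from_sequences(
    list(community.drivers.values()), community.driver_host
)
fixtures = sim.make_fixture_tables(community, seed=3)

hits = screen_contigs(community.contigs, drivers, r_min=0.6, min_len=10_000)
print(f"{len(community.contigs)} contigs screened against {len(drivers)} drivers")
for h in hits:
    if not h.passed:
        continue
    fb = bin_contig(h.contig_id, fixtures["orfs"][h.contig_id])
    truth = community.truth[h.contig_id]["label"]
    print(
        f"  {h.contig_id:24s} r={h.r_best:5.3f} via {h.best_driver_id:12s}"
        f" -> {fb.category:9s} (truth: {truth})"
    )
print(
    "A contig passes when its tetranucleotide signature correlates at 0.6 or\n"
    "over with any driver; binning then separates true prophage fragments\n"
    "(phage) from co-recovered host chromosome fragments (non_phage)."
)
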