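"""The packaged table of 34 DM1-relevant developmental splice events.

Loads the cassette-exon table, re-derives every exon length from its hg38
coordinates, and summarizes the gene/exon structure and reading-frame impact.
"""

from fetalsplice.events import (
    count_unique_genes,
    frame_disrupting,
    load_dm1_cortex_events,
    merge_cassette_exons,
)

table = load_dm1_cortex_events()

print(f"events: {len(table)}")
print(f"distinct genes (variant suffixes stripped): {count_unique_genes(table)}")
print(f"unique cassette exons after interval merging: {merge_cassette_exons(table)}")

n_inc = sum(ev.dm1_direction == "increased" for ev in table)
n_dec = sum(ev.dm1_direction == "decreased" for ev in table)
print(f"inclusion in DM1 cortex: {n_inc} increased, {n_dec} decreased")

n_frame = sum(frame_disrupting(ev.length) for ev in table)
print(f"frame-disrupting exons (length not divisible by 3): {n_frame} of {len(table)}")

gabrg2 = table["GABRG2"]
print(
    f"\nGABRG2 micro-exon: {gabrg2.length} nt "
    f"({gabrg2.length // 3} amino acids, frame preserved: "
    f"{not frame_disrupting(gabrg2.length)})"
)
# The 24-nt GABRG2 exon codes for an 8-residue stretch: skipping it switches
# the receptor subunit between its short and long isoform without breaking
# the reading frame.
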