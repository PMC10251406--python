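"""SIP-metaproteomics: which community members got the tracer carbon?

Generates a SIPPER-style peptide score table with planted labeled-protein
fractions, applies the six tight-filter cutoffs, and rolls labeled
peptides up to proteins, taxon pools (cyanobacterial vs heterotrophic) and
KEGG pathways.
"""

import dielmat as dm
from dielmat import simulate as sim

peptides, taxon_map, kegg_map, truth = sim.emit_peptide_tables(
    n_proteins_per_bin=1000, seed=42)

flagged = dm.apply_sipper_filters(peptides)
flagged = dm.attach_taxon_bins(flagged, taxon_map)

overall = dm.summarize_labeled_proteins(flagged, by_taxon=False)
final = overall[overall["timepoint"] == overall["timepoint"].max()]
print("labeled-protein fraction at 24 h, per incubation:")
for _, r in final.iterrows():
    print(f"  {r['incubation']:<12} {100 * r['relative_abundance']:.1f} % "
          f"of {r['n_proteins']} proteins")

by_bin = dm.summarize_labeled_proteins(flagged, by_taxon=True,
                                       weight_by_spectra=True)
sub = by_bin[by_bin["timepoint"] == by_bin["timepoint"].max()]
print("\nby taxon pool (cyanobacterial vs heterotrophic):")
print(sub[["incubation", "taxon_bin", "relative_abundance",
           "weighted_labeled_peptide_fraction"]].to_string(index=False))

matrix = dm.pathway_matrix(flagged, kegg_map)
print(f"\npathway matrix: {matrix.shape[0]} pathways x "
      f"{matrix.shape[1]} (taxon, timepoint, incubation) columns; "
      "values are sqrt relative abundance of labeled proteins")
print()
print("Reading: the cyanobacterial pool is the more labeled at every")
print("condition — photoautotrophs fix the tracer first, heterotrophs")
print("receive it second-hand.")
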