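"""TCR-peptide contact mapping on a toy structure with known layout.

Writes a synthetic complex where exactly 7 TRA and 8 TRB CDR residues
sit within 5 A of the peptide, recovers that layout from coordinates,
and regresses the CDR1:CDR3 contact ratio on junction length.
"""

import tempfile
from pathlib import Path

from pitmatch import (
    ContactSummary,
    cdr_ratio_regression,
    contact_residues,
    load_structure,
    map_contacts_to_regions,
    simulate_structure_fixture,
)
from pitmatch.contacts import read_region_annotations

tmp = Path(tempfile.mkdtemp(prefix="pitmatch_struct_"))
layout = {("TRA", "CDR1"): 2, ("TRA", "CDR2"): 1, ("TRA", "CDR3"): 4,
          ("TRB", "CDR1"): 2, ("TRB", "CDR2"): 2, ("TRB", "CDR3"): 4}
pdb, annot = tmp / "model.pdb", tmp / "regions.tsv"
simulate_structure_fixture(layout, pdb, annot)

chains = load_structure(pdb, {"A": "TRA", "B": "TRB", "P": "peptide"})
records = contact_residues(chains, cutoff_A=5.0,
                           region_annotations=read_region_annotations(annot))
summary = map_contacts_to_regions(records, tra_junction_length_aa=10)

cdr = ("CDR1", "CDR2", "CDR3")
print(f"TRA CDR contacts: {sum(summary.count('TRA', r) for r in cdr)} "
      f"(planted 7); TRB: {sum(summary.count('TRB', r) for r in cdr)} (planted 8)")
print(f"TRA CDR1:CDR3 contact ratio: {summary.cdr1_cdr3_ratio:.2f}")

# Across models, short junctions lean on germline-encoded CDR1 contacts
# while long junctions lean on recombined CDR3 contacts.
summaries = []
for i, length in enumerate(range(10, 18)):
    s = ContactSummary(model_id=f"model{i}")
    s.region_counts[("TRA", "CDR1")] = max(1, 8 - (length - 10))
    s.region_counts[("TRA", "CDR3")] = length - 6
    s.tra_junction_length_aa = length
    summaries.append(s)
slope, p, _ = cdr_ratio_regression(summaries)
print(f"\nCDR1:CDR3 ratio vs junction length: slope={slope:.3f}, p={p:.2g}")
print("A negative slope means longer junctions shift peptide contacts away")
print("from germline CDR1 loops onto the recombined CDR3 loop.")
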