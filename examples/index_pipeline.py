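"""From article counts to impact-weighted indices and fold changes.

AI = N x IF weights each article count by its journal's impact factor;
AII sums the AIs across journals for a field-year; Δ-AII is the
year-over-year AII ratio, with zeros replaced by 1.081 (one article in
the lowest-impact-factor tracked journal) so every ratio stays defined.
"""

import numpy as np

from minerva import (
    AIITable,
    CountPanel,
    FieldSpec,
    JournalSpec,
    annual_impact,
    compute_aii_table,
    delta_aii,
)

# one journal-year contribution: 6 articles in a journal with IF 40.137
print(f"AI = 6 x 40.137 = {annual_impact(6, 40.137)}")  # -> 240.822

# a small two-field panel across three journals and two years
journals = [JournalSpec("Nature", 40.137), JournalSpec("JAMA", 44.405), JournalSpec("Child's nervous system", 1.081)]
fields = [FieldSpec("epigenetics"), FieldSpec("glioblastoma")]
counts = np.array([[[0, 2], [0, 0], [1, 3]], [[5, 6], [2, 2], [10, 8]]])
panel = CountPanel(fields=fields, journals=journals, years=range(2012, 2014), counts=counts)

table = compute_aii_table(panel)
print("\nAII values (impact-weighted publication mass):")
print(table.to_frame().to_string(index=False))

series = delta_aii(table)
print("\nΔ-AII fold changes (>1 = the field gained momentum):")
print(series.to_frame().to_string(index=False))

# the published-scale worked example: a small field outpacing a huge one
worked = AIITable(
    fields=("epigenetics", "glioblastoma"),
    years=range(2012, 2014),
    values=np.array([[15.760, 88.141], [3298.539, 3972.712]]),
)
d = delta_aii(worked)
print(f"\nepigenetics  Δ-AII 2013 = {d.value('epigenetics', 2013):.3f}  (5.6x growth)")
print(f"glioblastoma Δ-AII 2013 = {d.value('glioblastoma', 2013):.3f}  (larger field, less momentum)")
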