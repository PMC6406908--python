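"""Build PubMed hit-count queries and rank candidate field keywords.

The count panel the pipeline consumes is assembled from one PubMed query
per (field, journal, year); this shows the exact command strings, plus the
word-frequency ranking used to shortlist field keywords from titles.
"""

from minerva import FieldSpec, build_pubmed_query, keyword_frequency

# plain keyword: the query pins the journal and a one-year publication window
print(build_pubmed_query("pilocytic astrocytoma", "Nature", 2015))

# broad keyword: the auxiliary term keeps the hits inside the target domain
broad = FieldSpec("single cell", directed=True, aux_term="brain tumor")
print(build_pubmed_query(broad, "Nature", 2017))

titles = [
    "IDH mutations and epigenetics in diffuse glioma",
    "Tumor microenvironment and immunology of glioblastoma",
    "Epigenetics of IDH-mutant glioma: methylation and beyond",
    "PD-1 blockade in recurrent glioblastoma",
]
print("\ntop keywords (stopwords removed):")
for term, count in keyword_frequency(titles, stopwords={"and", "of", "in", "the"}, top_n=5):
    print(f"  {term:20s} {count}")
# counts are raw occurrence tallies; the top terms are candidate fields to track
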