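"""Build a gazetteer from an OWL ontology's labels and synonyms.

The ontology is used purely as a term source: every class label and every
annotation whose property name contains "synonym" becomes a gazetteer term.
"""

import tempfile
from pathlib import Path

from aspectsent import build_gazetteer, owl_to_terms

ONTOLOGY = """
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix oio: <http://www.geneontology.org/formats/oboInOwl#> .
@prefix ex: <http://example.org/ddo#> .

ex:C101 a owl:Class ; rdfs:label "oral hypoglycemic" ;
    oio:hasExactSynonym "oral antihyperglycemic" .
ex:C102 a owl:Class ; rdfs:label "blood sugar" .
ex:C103 a owl:Class ; rdfs:label "insulin" .
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "mini.ttl"
    path.write_text(ONTOLOGY)
    pairs = owl_to_terms(str(path))

gazetteer = build_gazetteer(pairs)
print(f"{gazetteer.report.n_concepts} concepts, {gazetteer.report.n_terms} terms")
for term, cid in sorted(gazetteer.index.items()):
    print(f"  {' '.join(term):28s} -> {cid}")
# A synonym annotation makes "oral antihyperglycemic" findable even though
# only "oral hypoglycemic" is the class label — exactly the coverage gap
# that hurts recall when the ontology lacks the synonym.
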