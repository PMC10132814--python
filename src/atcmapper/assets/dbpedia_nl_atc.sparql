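# Documented (never executed) SPARQL query retrieving Dutch drug labels,
# brand names and ATC codes from the Dutch DBpedia SPARQL endpoint
# (http://nl.dbpedia.org/sparql/). Shipped as a text asset for provenance;
# the package performs no network access.

select distinct
  ?a as ?Resource
  str(?label) as ?Name
  CONCAT(str(?prefix), str(?suffix)) as ?ATC
  CONCAT("http://purl.bioontology.org/ontology/UATC/", str(?prefix), str(?suffix)) as ?URI
  str(?merknamen) as ?Merknamen
where {
  ?a <http://nl.dbpedia.org/property/atcPrefix> ?prefix .
  ?a rdf:type dbpedia-owl:Drug .
  OPTIONAL { ?a rdfs:label ?label }
  OPTIONAL { ?a <http://nl.dbpedia.org/property/atcSuffix> ?suffix . }
  OPTIONAL { ?a <http://nl.dbpedia.org/property/merknamen> ?merknamen . }
}
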