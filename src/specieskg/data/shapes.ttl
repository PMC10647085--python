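# SHACL expression of the shape constraints enforced natively by
# specieskg.shapes.validate_shapes, for use with external SHACL processors.
@prefix sh:   <http://www.w3.org/ns/shacl#> .
@prefix os:   <http://www.theworldavatar.com/ontology/ontospecies/OntoSpecies.owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd:  <http://www.w3.org/2001/XMLSchema#> .
@prefix :     <http://www.theworldavatar.com/kg/ontospecies/shapes#> .

:SpeciesShape a sh:NodeShape ;
    sh:targetClass os:Species ;
    sh:property [
        sh:path rdfs:label ;
        sh:minCount 1 ; sh:maxCount 1 ;
        sh:message "species must have exactly one rdfs:label" ;
    ] ;
    sh:property [
        sh:path os:hasIdentifier ;
        sh:minCount 1 ;
        sh:message "species must have at least one identifier" ;
    ] .

:PropertyShape a sh:NodeShape ;
    sh:targetClass os:Property ;
    sh:property [
        sh:path os:value ;
        sh:minCount 1 ; sh:datatype xsd:decimal ;
        sh:message "property node needs a decimal os:value" ;
    ] ;
    sh:property [
        sh:path os:unit ;
        sh:minCount 1 ;
        sh:message "property node needs os:unit" ;
    ] ;
    sh:property [
        sh:path os:hasProvenance ;
        sh:minCount 1 ;
        sh:message "property node needs os:hasProvenance" ;
    ] .

:RecommendedShape a sh:NodeShape ;
    sh:targetClass os:Property ;
    sh:sparql [
        sh:message "recommended property must carry provenance label 'PubChem agent'" ;
        sh:select """
            PREFIX os: <http://www.theworldavatar.com/ontology/ontospecies/OntoSpecies.owl#>
            PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
            SELECT $this WHERE {
                $this os:isRecommended true .
                FILTER NOT EXISTS {
                    $this os:hasProvenance/rdfs:label "PubChem agent" .
                }
            }
        """ ;
    ] .

:BondShape a sh:NodeShape ;
    sh:targetClass os:AtomicBond ;
    sh:property [
        sh:path os:hasBondOrder ;
        sh:minCount 1 ; sh:datatype xsd:integer ; sh:minInclusive 1 ;
        sh:message "bond order must be a positive integer" ;
    ] .

:PeakShape a sh:NodeShape ;
    sh:targetClass os:Peak ;
    sh:property [
        sh:path os:value ;
        sh:minCount 1 ;
        sh:message "peak needs a position" ;
    ] .
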