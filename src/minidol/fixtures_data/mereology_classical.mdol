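distributed-ontology Mereology

logic Propositional
ontology Taxonomy =
  %% basic taxonomic information about mereology
  props PT %{ Particular }% , PD %{ Perdurant }% , T %{ TimeInterval }% ,
        S %{ SpaceRegion }% , AR %{ AbstractRegion }%
  . S or T or AR or PD implies PT   %% PT is the top concept
  . S and T implies false           %% PD, S, T, AR are pairwise disjoint
  . S and AR implies false
  . S and PD implies false
  . T and AR implies false
  . T and PD implies false
  . AR and PD implies false

logic EL
ontology ELParthood =
  %% Parthood in OWL EL
  Class ParticularCategory SubClassOf PT
  Class PT DisjointUnionOf S , T , AR , PD
  ObjectProperty isPartOf Characteristics Transitive

logic OWL
ontology ProperParthood = ELParthood then
  ObjectProperty isProperPartOf
    Characteristics Asymmetric
    SubPropertyOf isPartOf
  Class Atom EquivalentTo ( inverse isProperPartOf Only Nothing )
    %% an atom has no proper parts

logic ExpDL
ontology Parthood = ProperParthood then
  %% Transitive + Asymmetric not allowed in OWL
  ObjectProperty isProperPartOf
    Characteristics Transitive
    SubPropertyChain ispartof o isProperPartOf

logic FOL
ontology FOLParthood = Parthood then
  %% definition of overlap
  . forall x y ( Ov ( x y ) iff exists z ( isPartOf ( z x ) and isPartOf ( z y ) ) )

logic CommonLogic
ontology ClassicalExtensionalParthood = FOLParthood then {
  %% classical-form sum (disjunctive overlap) and fusion (member overlap)
  . ( forall ( X ) ( if ( or ( = X S ) ( = X T ) ( = X AR ) ( = X PD ) )
      ( forall ( x y z ) ( if ( and ( X x ) ( X y ) ( X z ) )
        ( and
          ( iff ( isAtomicPartOf x y ) ( and ( isPartOf x y ) ( Atom x ) ) )
          ( iff ( sum z x y )
            ( forall ( w ) ( iff ( overlaps w z )
              ( or ( overlaps w x ) ( overlaps w y ) ) ) ) )
          ( exists ( s ) ( sum s x y ) ) ) ) ) ) )
  . ( forall ( Set a ) ( iff ( fusion Set a )
      ( forall ( b ) ( iff ( overlaps b a )
        ( exists ( c ) ( and ( Set c ) ( overlaps c b ) ) ) ) ) ) )
}

interpretation TaxonomyToELParthood : Taxonomy with translation PropToOWL to ELParthood
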