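distributed-ontology HER2

logic OWL
ontology HER2 = ProperParthood then
  Class IHC_HER2_Score
    DisjointUnionOf HER2_Negative , HER2_Borderline , HER2_Positive
  Class HER2_Negative EquivalentTo { 0 1+ }
  Class HER2_Borderline EquivalentTo { 2+ }
  Class HER2_Positive EquivalentTo { 3+ }
  Class HER2 SubClassOf Proteins
  Class Cell DisjointUnionOf Normal_Cell , HER2+_Cell
  Class Tissue DisjointUnionOf Normal_Tissue , HER2+_Tissue
    SubClassOf ( hasHER2Score Exactly 1 IHC_Her2_Score )
      %% we assume all tissue to be IHC measured
  Class Cell_Membrane SubClassOf ( isProperPartOf Exactly 1 Cell )
  Class HER2+_Tissue
    EquivalentTo ( Tissue And ( hasHER2Score Some HER2_Positive ) )
      %% determination of HER2 positivity by the IHC method
  Class HER2+_Cell SubClassOf ( inverse isProperPartOf Some HER2+_Cell_Membrane )
  Individual X Types ( Tissue And ( hasHER2Score Some { 3+ } ) )
  Individual Y Types Tissue DifferentFrom X
  minimise HER2+_Cell_Membrane , HER2+_Cell , HER2+_Tissue
  vary Normal_Cancer_Cell_Membrane , Normal_Cancer_Cell , Normal_Cancer-Tissue
  then %implies
  Individual X Types HER2+_Tissue
  Individual Y
    Types ( Normal_Tissue And ( hasHER2Score Some ( HER2_Negative Or HER2_Borderline ) ) )
      %% Y is normal tissue (non-HER2 positive) without evidence to the contrary
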