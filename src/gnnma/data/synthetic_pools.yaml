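# Default scaffold and decoration pools for the synthetic screening
# library generator.  Scaffold templates carry numbered dummy attachment
# sites ([1*], [2*], ...); decorations carry a single [1*] site that is
# relabelled to the chosen scaffold site before zipping.  The eight bare
# scaffolds are pairwise substructure-free, so a decoy built on another
# scaffold never contains a target's scaffold motif.
scaffolds:
  benzene: "[1*]c1cc([2*])cc([3*])c1"
  pyridine: "[1*]c1cc([2*])cnc1"
  pyrimidine: "[1*]c1ncc([2*])cn1"
  pyrrole: "[1*]n1cc([2*])cc1[3*]"
  furan: "[1*]c1oc([2*])cc1"
  thiophene: "[1*]c1sc([2*])cc1"
  piperidine: "[1*]N1CCC([2*])CC1"
  morpholine: "[1*]N1CC([2*])OCC1"
decorations:
  - "[1*]F"
  - "[1*]Cl"
  - "[1*]Br"
  - "[1*]C"
  - "[1*]CC"
  - "[1*]OC"
  - "[1*]O"
  - "[1*]N"
  - "[1*]C(C)C"
  - "[1*]C(=O)N"
  - "[1*]C#N"
  - "[1*]CO"
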