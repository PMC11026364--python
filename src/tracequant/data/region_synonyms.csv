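synonym,canonical
CA1_py,CA1_py
CA1 pyramidal,CA1_py
CA1 pyramidal layer,CA1_py
CA1_or,CA1_or
CA1 oriens,CA1_or
CA1 oriens layer,CA1_or
CA1_rad,CA1_rad
CA1 radiatum,CA1_rad
CA1 radiatum layer,CA1_rad
CA1_lmol,CA1_lmol
CA1 lacunosum-moleculare,CA1_lmol
CA1 lacunosum moleculare,CA1_lmol
CA2_py,CA2_py
CA2 pyramidal,CA2_py
CA2 pyramidal layer,CA2_py
CA2_or,CA2_or
CA2 oriens,CA2_or
CA3_py,CA3_py
CA3 pyramidal,CA3_py
CA3 pyramidal layer,CA3_py
CA3_or,CA3_or
CA3 oriens,CA3_or
SUB,SUB
subiculum,SUB
dorsal SUB,SUB
PostSUB,PostSUB
postSUB,PostSUB
postsubiculum,PostSUB
MS-DB,MS-DB
MSDB,MS-DB
MS/DB,MS-DB
medial septum,MS-DB
medial septum and diagonal band,MS-DB
Thalamus,Thalamus
anterior thalamus,Thalamus
Thal,Thalamus
RSC,RSC
retrosplenial cortex,RSC
retrosplenial,RSC
Vis,Vis
Vis cortex,Vis
visual cortex,Vis
Aud,Aud
Aud cortex,Aud
Aud Cortex,Aud
auditory cortex,Aud
SS,SS
SS cortex,SS
SS Cortex,SS
somatosensory cortex,SS
TeA,TeA
temporal association cortex,TeA
Prh,Prh
perirhinal cortex,Prh
Ect,Ect
ectorhinal cortex,Ect
LEC,LEC
lateral entorhinal cortex,LEC
MEC,MEC
medial entorhinal cortex,MEC
OTHER_SPARSE,OTHER_SPARSE
contralateral CA1,OTHER_SPARSE
contra CA1,OTHER_SPARSE
hypothalamus,OTHER_SPARSE
dentate gyrus,OTHER_SPARSE
DG,OTHER_SPARSE
cingulate,OTHER_SPARSE
cingulate cortex,OTHER_SPARSE
midbrain,OTHER_SPARSE
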