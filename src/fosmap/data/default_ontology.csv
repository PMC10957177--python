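acronym,name,level,parent_acronym
CTX,Cerebral cortex,division,
CNU,Cerebral nuclei,division,
TH,Thalamus,division,
HY,Hypothalamus,division,
MB,Midbrain,division,
HB,Hindbrain,division,
OLF,Olfactory areas,coarse53,CTX
MO,Somatomotor areas,coarse53,CTX
SS,Somatosensory areas,coarse53,CTX
GU,Gustatory areas,coarse53,CTX
VISC,Visceral area,coarse53,CTX
AUD,Auditory areas,coarse53,CTX
VIS,Visual areas,coarse53,CTX
ACA,Anterior cingulate area,coarse53,CTX
PL,Prelimbic area,coarse53,CTX
ILA,Infralimbic area,coarse53,CTX
ORB,Orbital area,coarse53,CTX
AI,Agranular insular area,coarse53,CTX
RSP,Retrosplenial area,coarse53,CTX
TEa,Temporal association areas,coarse53,CTX
PERI,Perirhinal area,coarse53,CTX
ECT,Ectorhinal area,coarse53,CTX
HIP,Hippocampal region,coarse53,CTX
RHP,Retrohippocampal region,coarse53,CTX
STRd,Striatum dorsal region,coarse53,CNU
STRv,Striatum ventral region,coarse53,CNU
LSX,Lateral septal complex,coarse53,CNU
sAMY,Striatum-like amygdalar nuclei,coarse53,CNU
PALd,Pallidum dorsal region,coarse53,CNU
PALv,Pallidum ventral region,coarse53,CNU
PALm,Pallidum medial region,coarse53,CNU
PALc,Pallidum caudal region,coarse53,CNU
DORsm,Thalamus sensory-motor cortex related,coarse53,TH
DORpm,Thalamus polymodal association cortex related,coarse53,TH
PVZ,Periventricular zone,coarse53,HY
PVR,Periventricular region,coarse53,HY
MEZ,Hypothalamic medial zone,coarse53,HY
LZ,Hypothalamic lateral zone,coarse53,HY
MBsen,Midbrain sensory related,coarse53,MB
MBmot,Midbrain motor related,coarse53,MB
MBsta,Midbrain behavioral state related,coarse53,MB
P,Pons,coarse53,HB
MY,Medulla,coarse53,HB
MOB,Main olfactory bulb,fine201,OLF
AON,Anterior olfactory nucleus,fine201,OLF
TT,Taenia tecta,fine201,OLF
DP,Dorsal peduncular area,fine201,OLF
PIR,Piriform area,fine201,OLF
MOp,Primary motor area,fine201,MO
MOs,Secondary motor area,fine201,MO
SSp,Primary somatosensory area,fine201,SS
SSs,Supplemental somatosensory area,fine201,SS
VISp,Primary visual area,fine201,VIS
VISam,Anteromedial visual area,fine201,VIS
AUDp,Primary auditory area,fine201,AUD
ACAd,Anterior cingulate area dorsal part,fine201,ACA
ACAv,Anterior cingulate area ventral part,fine201,ACA
ORBl,Orbital area lateral part,fine201,ORB
ORBm,Orbital area medial part,fine201,ORB
AId,Agranular insular area dorsal part,fine201,AI
AIp,Agranular insular area posterior part,fine201,AI
RSPd,Retrosplenial area dorsal part,fine201,RSP
RSPv,Retrosplenial area ventral part,fine201,RSP
CA1,Field CA1,fine201,HIP
CA3,Field CA3,fine201,HIP
DG,Dentate gyrus,fine201,HIP
SUB,Subiculum,fine201,RHP
ENT,Entorhinal area,fine201,RHP
PRE,Presubiculum,fine201,RHP
CP,Caudoputamen,fine201,STRd
ACB,Nucleus accumbens,fine201,STRv
OT,Olfactory tubercle,fine201,STRv
FS,Fundus of striatum,fine201,STRv
LSc,Lateral septal nucleus caudal part,fine201,LSX
LSr,Lateral septal nucleus rostral part,fine201,LSX
CEA,Central amygdalar nucleus,fine201,sAMY
MEA,Medial amygdalar nucleus,fine201,sAMY
GPe,Globus pallidus external segment,fine201,PALd
SI,Substantia innominata,fine201,PALv
MA,Magnocellular nucleus,fine201,PALv
NDB,Diagonal band nucleus,fine201,PALm
BST,Bed nuclei of the stria terminalis,fine201,PALc
VENT,Ventral group of the dorsal thalamus,fine201,DORsm
LAT,Lateral group of the dorsal thalamus,fine201,DORsm
PVT,Paraventricular nucleus of the thalamus,fine201,DORpm
RE,Nucleus of reuniens,fine201,DORpm
CM,Central medial nucleus of the thalamus,fine201,DORpm
SO,Supraoptic nucleus,fine201,PVZ
PVH,Paraventricular hypothalamic nucleus,fine201,PVZ
PVi,Periventricular hypothalamic nucleus intermediate part,fine201,PVZ
ARH,Arcuate hypothalamic nucleus,fine201,PVZ
MEPO,Median preoptic nucleus,fine201,PVR
AVPV,Anteroventral periventricular nucleus,fine201,PVR
MPO,Medial preoptic area,fine201,PVR
VLPO,Ventrolateral preoptic nucleus,fine201,PVR
SCH,Suprachiasmatic nucleus,fine201,PVR
SBPV,Subparaventricular zone,fine201,PVR
DMH,Dorsomedial nucleus of the hypothalamus,fine201,PVR
VMH,Ventromedial hypothalamic nucleus,fine201,MEZ
MPN,Medial preoptic nucleus,fine201,MEZ
LHA,Lateral hypothalamic area,fine201,LZ
LPO,Lateral preoptic area,fine201,LZ
TU,Tuberal nucleus,fine201,LZ
RCH,Retrochiasmatic area,fine201,LZ
SCs,Superior colliculus sensory related,fine201,MBsen
IC,Inferior colliculus,fine201,MBsen
PAG,Periaqueductal gray,fine201,MBmot
VTA,Ventral tegmental area,fine201,MBmot
EW,Edinger-Westphal nucleus,fine201,MBmot
SCm,Superior colliculus motor related,fine201,MBmot
PPN,Pedunculopontine nucleus,fine201,MBsta
LC,Locus ceruleus,fine201,P
SLD,Sublaterodorsal nucleus,fine201,P
PB,Parabrachial nucleus,fine201,P
SOC,Superior olivary complex,fine201,P
NTS,Nucleus of the solitary tract,fine201,MY
AP,Area postrema,fine201,MY
IO,Inferior olivary complex,fine201,MY
MARN,Magnocellular reticular nucleus,fine201,MY
PGRN,Paragigantocellular reticular nucleus,fine201,MY
LRN,Lateral reticular nucleus,fine201,MY
RO,Nucleus raphe obscurus,fine201,MY
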