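# Default resting-state network definitions over the 90-region AAL atlas.
# VN: bilateral striate and extrastriate visual cortex (calcarine, cuneus,
#     lingual, superior/middle/inferior occipital).
# DMN: hippocampus, parahippocampal, fusiform and angular gyri, precuneus,
#     middle temporal gyrus.
# AN: dorsolateral superior frontal, middle frontal (incl. orbital part),
#     inferior frontal (opercular, triangular, orbital), superior and
#     inferior parietal, superior temporal gyri.
# SN: superior medial frontal cortex, insula, anterior/middle/posterior
#     cingulate.
VN:
  - Calcarine_L
  - Calcarine_R
  - Cuneus_L
  - Cuneus_R
  - Lingual_L
  - Lingual_R
  - Occipital_Sup_L
  - Occipital_Sup_R
  - Occipital_Mid_L
  - Occipital_Mid_R
  - Occipital_Inf_L
  - Occipital_Inf_R
DMN:
  - Hippocampus_L
  - Hippocampus_R
  - ParaHippocampal_L
  - ParaHippocampal_R
  - Fusiform_L
  - Fusiform_R
  - Angular_L
  - Angular_R
  - Precuneus_L
  - Precuneus_R
  - Temporal_Mid_L
  - Temporal_Mid_R
AN:
  - Frontal_Sup_L
  - Frontal_Sup_R
  - Frontal_Mid_L
  - Frontal_Mid_R
  - Frontal_Mid_Orb_L
  - Frontal_Mid_Orb_R
  - Frontal_Inf_Oper_L
  - Frontal_Inf_Oper_R
  - Frontal_Inf_Tri_L
  - Frontal_Inf_Tri_R
  - Frontal_Inf_Orb_L
  - Frontal_Inf_Orb_R
  - Parietal_Sup_L
  - Parietal_Sup_R
  - Parietal_Inf_L
  - Parietal_Inf_R
  - Temporal_Sup_L
  - Temporal_Sup_R
SN:
  - Frontal_Sup_Medial_L
  - Frontal_Sup_Medial_R
  - Insula_L
  - Insula_R
  - Cingulum_Ant_L
  - Cingulum_Ant_R
  - Cingulum_Mid_L
  - Cingulum_Mid_R
  - Cingulum_Post_L
  - Cingulum_Post_R
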