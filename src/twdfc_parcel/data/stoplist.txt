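# Anatomy / localization terms removed during term screening.
# Matching is case-insensitive substring matching; edit freely.
left
right
cortex
cortical
hemisphere
pfc
gyrus
gyri
sulcus
sulci
lobe
lobule
anterior
posterior
dorsal
ventral
medial
lateral
frontal
temporal
parietal
occipital
insula
thalamus
cerebellum
white matter
grey matter
gray matter
subcortical
brainstem
area
region
voxel
atlas
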