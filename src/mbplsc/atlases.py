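"""Reference atlas label lists.

Shipped as conveniences for the common use case — Desikan-Killiany cortical
morphometry (68 regions) against JHU white-matter tract FA (48 tracts).
Arbitrary label sets are accepted everywhere; nothing in the pipeline depends
on these specific names.
"""

_DK_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

#: 68 Desikan-Killiany cortical region labels (lh_* then rh_*).
DK_CORTICAL_68 = [f"{h}_{r}" for h in ("lh", "rh") for r in _DK_REGIONS]

#: 48 JHU ICBM-DTI-81 white-matter tract labels.
JHU_TRACTS_48 = [
    "middle_cerebellar_peduncle",
    "pontine_crossing_tract",
    "genu_of_corpus_callosum",
    "body_of_corpus_callosum",
    "splenium_of_corpus_callosum",
    "fornix_column_and_body",
    "corticospinal_tract_r", "corticospinal_tract_l",
    "medial_lemniscus_r", "medial_lemniscus_l",
    "inferior_cerebellar_peduncle_r", "inferior_cerebellar_peduncle_l",
    "superior_cerebellar_peduncle_r", "superior_cerebellar_peduncle_l",
    "cerebral_peduncle_r", "cerebral_peduncle_l",
    "anterior_limb_of_internal_capsule_r", "anterior_limb_of_internal_capsule_l",
    "posterior_limb_of_internal_capsule_r", "posterior_limb_of_internal_capsule_l",
    "retrolenticular_part_of_internal_capsule_r",
    "retrolenticular_part_of_internal_capsule_l",
    "anterior_corona_radiata_r", "anterior_corona_radiata_l",
    "superior_corona_radiata_r", "superior_corona_radiata_l",
    "posterior_corona_radiata_r", "posterior_corona_radiata_l",
    "posterior_thalamic_radiation_r", "posterior_thalamic_radiation_l",
    "sagittal_stratum_r", "sagittal_stratum_l",
    "external_capsule_r", "external_capsule_l",
    "cingulum_cingulate_gyrus_r", "cingulum_cingulate_gyrus_l",
    "cingulum_hippocampus_r", "cingulum_hippocampus_l",
    "fornix_cres_stria_terminalis_r", "fornix_cres_stria_terminalis_l",
    "superior_longitudinal_fasciculus_r", "superior_longitudinal_fasciculus_l",
    "superior_fronto_occipital_fasciculus_r",
    "superior_fronto_occipital_fasciculus_l",
    "uncinate_fasciculus_r", "uncinate_fasciculus_l",
    "tapetum_r", "tapetum_l",
]

assert len(DK_CORTICAL_68) == 68
assert len(JHU_TRACTS_48) == 48
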