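# Canonical staging calibration for Calliphora vicina embryogenesis.
# One row per landmark x rearing temperature; eleven category columns for the
# 0 %..100 % developmental intervals. Symbols: "" (blank) = character not
# visible; + = visible in <25 % of examined individuals; ++ = 25-75 %;
# +++ = >75 %. hwk_visible marks characters that survive hot-water-killing
# fixation followed by 80 % ethanol storage.
#
# Directives: calibrated temperature blocks (temp_c, total hours from
# oviposition to hatching) and the lower developmental threshold.
#! base_temp_c	1.0
#! temperature	7.3	120
#! temperature	25	16
#
# Provenance notes on cells that are ambiguous in degraded renderings of the
# source table (resolved against the per-interval results narrative):
#  - dorsal_folds @ 7.3 C, 30 %: transcribed +++ (dorsal folds reported in
#    every specimen at the 30 % interval); some renderings show ++.
#  - stomodeal_invagination @ 7.3 C, 30 %: + (early features appear at
#    proportionately earlier intervals at the cool temperature).
#  - clypeolabrum spans (40-70 %): decomposition consistent with the
#    narrative (clear protuberance at 50 %, still distinct at 60 %, covered
#    by a dorsal fold at 70 %).
landmark_id	landmark_name	hwk_visible	temp_c	cat_0	cat_10	cat_20	cat_30	cat_40	cat_50	cat_60	cat_70	cat_80	cat_90	cat_100
homogeneous_yolk_mass	Homogeneous yolk mass	no	7.3	++
homogeneous_yolk_mass	Homogeneous yolk mass	no	25	++
clear_gaps	Clear gaps	no	7.3	++	+++
clear_gaps	Clear gaps	no	25	++	+++
bright_peripheral_ring	Bright peripheral ring	yes	7.3			+
bright_peripheral_ring	Bright peripheral ring	yes	25			+++
cephalic_furrow	Cephalic furrow	yes	7.3			+++	+++
cephalic_furrow	Cephalic furrow	yes	25			+	+++
dorsal_folds	Dorsal folds	no	7.3				+++
dorsal_folds	Dorsal folds	no	25				+++
stomodeal_invagination	Stomodeal invagination	yes	7.3				+	+++	+++	+++	+++
stomodeal_invagination	Stomodeal invagination	yes	25					+++	+++	+++	+++
thoracic_segmentation	Thoracic segmentation	yes	7.3					+	+++	+++	+++	+++	+++	+++
thoracic_segmentation	Thoracic segmentation	yes	25					+	+++	+++	+++	+++	+++	+++
clypeolabrum	Clypeolabrum	yes	7.3					++	+++	+++	+
clypeolabrum	Clypeolabrum	yes	25					++	+++	+++	++
abdominal_segmentation	Abdominal segmentation	yes	7.3						++	+++	+++	+++	+++	+++
abdominal_segmentation	Abdominal segmentation	yes	25						+	+++	+++	+++	+++	+++
sack_shaped_gut	Sack-shaped gut	yes	7.3								+++
sack_shaped_gut	Sack-shaped gut	yes	25								+++
coil_shaped_gut	Coil-shaped gut	yes	7.3								+	+++	+++	+++
coil_shaped_gut	Coil-shaped gut	yes	25									+++	+++	+++
spine_bands	Spine bands	yes	7.3										+++	+++
spine_bands	Spine bands	yes	25										+++	+++
posterior_spiracles	Posterior spiracles	yes	7.3										+++	+++
posterior_spiracles	Posterior spiracles	yes	25										+++	+++
cephalopharyngeal_skeleton	Cephalopharyngeal skeleton	yes	7.3											+++
cephalopharyngeal_skeleton	Cephalopharyngeal skeleton	yes	25										+	+++
fully_developed_tracheal_system	Fully developed tracheal system	no	7.3											+++
fully_developed_tracheal_system	Fully developed tracheal system	no	25											+++
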