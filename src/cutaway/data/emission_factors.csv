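land_use,gas,phase_start,phase_end,value,low,high,uncertainty_kind,source_tag
pine_afforestation,CO2,0,,-0.5,-1.6,1.4,range,"net stand+soil C balance, Scots pine on cutaway (Aro & Kaunisto; Makiranta et al.; Jauhiainen et al. soil range)"
short_rotation_birch,CO2,0,,-0.2,-1.3,1.7,range,"net stand+soil C balance, short-rotation downy birch (Hytonen & Aro; Jauhiainen et al. soil range)"
vegetated_surface,CO2,0,,1.5,1.0,2.0,range,"unfertilized revegetated/abandoned cutaway surfaces (Jarveoja et al.; Tuittila et al.)"
grass_agriculture,CO2,0,,5.39,2.71,8.14,ci95,"IPCC Wetlands Supplement, grassland on drained boreal organic soil, on-site CO2-C"
grass_agriculture,DOC,0,,0.31,0.19,0.46,ci95,"IPCC Wetlands Supplement, DOC export from drained organic soil"
grass_agriculture,N2O,0,,0.0095,0.0047,0.014,ci95,"IPCC Wetlands Supplement, grassland on drained boreal organic soil"
phalaris_drained,CO2,0,,1.25,0.46,2.04,range,"reed canary grass under drained cultivation on cutaway (Hyvonen; Jarveoja et al.; Mander et al.)"
phalaris_drained,DOC,0,,0.05,0.04,0.06,range,"DOC export, drained cutaway cultivation"
phalaris_drained,N2O,0,,0.002,0.0,0.004,range,"reed canary grass cultivation on cutaway, N2O"
peatland_restoration,CO2,0,1,3.0,1.5,5.0,ci95,"first-year straw-mulch decomposition pulse after moss-transfer restoration (Nugent et al. chronosequence)"
peatland_restoration,CO2,1,15,0.25,-0.4,1.2,ci95,"establishment phase, restored cutaway (Nugent et al. chronosequence)"
peatland_restoration,CO2,15,,-0.72,-1.35,0.0,ci95,"developing moss sink, restored cutaway (Nugent et al. chronosequence)"
peatland_restoration,CH4,0,,0.05,0.01,0.2,ci95,"rewetted nutrient-poor peatland CH4 (Nugent et al.)"
open_water_wetland,CO2,0,,0.07,-0.55,0.07,range,"littoral-zone CO2 balance, constructed open-water wetland"
open_water_wetland,CH4,10,,0.14,0.06,0.14,range,"littoral CH4 from year 10 onward; matches IPCC 2019 Refinement pond EF and Wetlands Supplement rich rewetted EF"
reference_paludiculture_agri_peat,CO2,0,,0.4,-1.0,1.8,range,"reference only: graminoid paludiculture on former agricultural peatland; never allocated in scenarios"
reference_paludiculture_agri_peat,CH4,0,,0.2,0.02,0.6,range,"reference only: paludiculture CH4 on former agricultural peatland"
reference_dry_cultivation_agri_peat,CO2,0,,6.9,4.1,9.7,range,"reference only: dry cultivation on former agricultural peatland"
reference_dry_cultivation_agri_peat,N2O,0,,0.013,0.008,0.018,range,"reference only: dry cultivation on former agricultural peatland, N2O"
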