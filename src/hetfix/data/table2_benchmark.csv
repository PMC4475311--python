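# Published CO2-fixation rates of autotrophic microbes (microalgae,
# cyanobacteria, non-green algae) and heterotrophic CO2-fixing bacteria,
# transcribed from the source comparison table.
# Transcription notes:
# - Dunaliella tertiolecta SAD-13.86: volumetric rate read as 11.0 (the strain
#   designation abuts the rate column in the typeset table); biomass 2.1.
# - Botryococcus braunii SAG-30.81: volumetric rate read as 21.0; biomass 3.1.
# - E. coli JB row: rate 5.8, biomass 0.95, printed specific rate 6.1,
#   CO2 0.03 % (ambient air).
# - specific_rate_printed is the value as printed; several rows differ from
#   1-decimal rounding of rate/biomass (evidently computed from unrounded
#   source data) and are preserved as printed.
species,group,volumetric_rate_mg_L_h,biomass_gDCW_L,specific_rate_printed_mg_gDCW_h,co2_percent,culture_condition,source
Chlorella pyrenoidosa SJTU-2,microalgae,10.8,1.5,7.3,10,1 L flask with 800 mL WV,CR52
Dunaliella tertiolecta SAD-13.86,microalgae,11.0,2.1,5.2,10,11 L fermentor with 8 L WV,CR53
Botryococcus braunii SAG-30.81,microalgae,21.0,3.1,6.8,10,11 L fermentor with 8 L WV,CR53
Scenedesmus obliquus SJTU-3,microalgae,12.1,1.8,6.6,10,1 L flask with 800 mL WV,CR52
Scenedesmus sp. NIER-10060,microalgae,25.5,2.7,9.4,15,Photobioreactor,CR54
Chlorella vulgaris LEB-104,microalgae,10.5,1.9,5.4,10,11 L fermentor with 8 L WV,CR53
Chlorella vulgaris NIER-10003,microalgae,19.2,1.9,10.2,15,Photobioreactor,CR54
Chlorella vulgaris,microalgae,53.0,5.7,9.3,5,Sequential photobioreactor using recycle water,CR55
Spirulina sp.,cyanobacteria,17.0,4.8,3.5,6,2 L vertical tubular photobioreactor with 1.8 L WV,CR56
Microcystis aeruginosa NIER-10037,cyanobacteria,20.4,2.3,8.8,15,Photobioreactor,CR54
Microcystis ichthyoblabe NIER-10040,cyanobacteria,21.7,2.2,9.8,15,Photobioreactor,CR54
Anabaena sp. ATCC 33047,cyanobacteria,60.4,2.7,22.4,0.03,Glass bubble column photobioreactor,CR57
Aphanothece microscopica,cyanobacteria,109.0,5.1,21.4,15,Glass bubble column photobioreactor,CR58
Phaeodactylum tricornutum,non-green algae,147.0,6.2,23.7,40,Photobioreactor,CR59
E. coli JB,bacteria,5.8,0.95,6.1,0.03,3 L fermentor with 1 L WV,CR19
E. coli BL21(DE3)/pET-RBC-PRK,bacteria,13.3,0.82,16.2,5,1 L flask with 200 mL WV,this study
E. coli BL21(DE3)/pET-RBC-PRK-CA,bacteria,19.6,0.87,22.5,5,1 L flask with 200 mL WV,this study
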