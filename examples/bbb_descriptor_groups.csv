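feature,group
AbsCarboxy,carboxylic_acid
M_PSA_7.4,psa
M_PSA_7.0,psa
M_PSA_6.5,psa
PPSA-1_Partial_positive_surface_area_[Quantum-Chemical_PC],psa
ESP-HASA_H-acceptors_surface_area_Quantum-Chemical_PC,h_bonding
ESP-FHASA_Fractional_HASA_(HASA/TMSA)_Quantum-Chemical_PC,h_bonding
HA_dependent_HDCA-2_[Zefirov's_PC],h_bonding
HA_dependent_HDSA-2_[Zefirov's_PC],h_bonding
M_logP,lipophilicity
delta_logD,lipophilicity
Topographic_electronic_index_(all_bonds)_Zefirov's_PC,molecular_charge
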