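# Packaged cumulative exclusion scenarios for the Taiwanese coastal/offshore
# landings analysis. Lists are the operational ground truth; the catalog's
# migratory_class column is a cross-check. Spellings use the accepted Latin
# binomials (e.g. Trachurus japonicus, Hemitriakis japonicus).
scenario_all:
  excluded_classes: []
  excluded_species: []
scenario_1:
  # tuna: highly migratory, high market value
  excluded_classes: [tuna]
  excluded_species:
    - Katsuwonus pelamis
    - Thunnus alalunga
    - Thunnus albacares
    - Thunnus obesus
    - Thunnus orientalis
scenario_2:
  # + oceanic migratory species (billfish, pelagic sharks, dolphinfish, saury...)
  excluded_classes: [tuna, oceanic_migratory]
  excluded_species:
    - Katsuwonus pelamis
    - Thunnus alalunga
    - Thunnus albacares
    - Thunnus obesus
    - Thunnus orientalis
    - Carcharhinidae
    - Cololabis saira
    - Coryphaena hippurus
    - Cypselurus unicolor
    - Euthynnus affinis
    - Istiompax indica
    - Istiophorus platypterus
    - Isurus oxyrinchus
    - Kajikia audax
    - Makaira mazara
    - Mola mola
    - Prionace glauca
    - Xiphias gladius
scenario_3:
  # + seasonally migratory species; the remainder is the indigenous assemblage
  excluded_classes: [tuna, oceanic_migratory, seasonal_migratory]
  excluded_species:
    - Katsuwonus pelamis
    - Thunnus alalunga
    - Thunnus albacares
    - Thunnus obesus
    - Thunnus orientalis
    - Carcharhinidae
    - Cololabis saira
    - Coryphaena hippurus
    - Cypselurus unicolor
    - Euthynnus affinis
    - Istiompax indica
    - Istiophorus platypterus
    - Isurus oxyrinchus
    - Kajikia audax
    - Makaira mazara
    - Mola mola
    - Prionace glauca
    - Xiphias gladius
    - Aluterus monoceros
    - Auxis spp.
    - Carcharhinus limbatus
    - Cheilopogon unicolor
    - Decapterus maruadsi
    - Hemitriakis japonicus
    - Lutjanus argentimaculatus
    - Megalaspis cordyla
    - Monacanthidae
    - Mugil cephalus
    - Polydactylus sextarius
    - Rachycentron canadum
    - Ruvettus pretiosus
    - Sardinella sindensis
    - Scomber australasicus
    - Scomberomorus spp.
    - Sphyraena barracuda
    - Trachurus japonicus
    - Trichiurus lepturus
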