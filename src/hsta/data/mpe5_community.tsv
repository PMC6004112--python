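# Expected mock-community composition: taxon, rank, biomass in grams.
# Order/class-rank entries carry the total biomass of the group; the seven
# Carabidae (Coleoptera) members are additionally listed at species rank
# with per-organism biomass.  CC1 = Carabus (Tomocarabus) convexus dilatatus,
# LL1 = Laemostenus latialis.
Coleoptera	order	22.89
Diptera	order	4.12
Orthoptera	order	2.44
Blattodea	order	1.02
Myriapoda	order	0.82
Isopoda	order	0.7
Arachnida	order	0.64
Scorpiones	order	0.63
Hymenoptera	order	0.21
Lepidoptera	order	0.1
Collembola	order	0.02
Carabus (Tomocarabus) convexus dilatatus	species	12.94
Carabus (Chaetocarabus) lefebvrei bayardi	species	4.85
Calathus fracasii	species	0.58
Abax parallelepipedus	species	0.29
Laemostenus latialis	species	0.23
Pterostichus micans	species	0.18
Calathus montivagus	species	0.07
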