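family,common_name,species_name,mean_density,density_se,density_rank,counts,max_group,max_group_significance,esw,esw_pooled
Papilionidae,Black Swallowtail,Papilio polyxenes,0.115,0.051,39,36,open,*,5.98,1
Papilionidae,Giant Swallowtail,Papilio cresphontes,0.008,0.006,58,3,savanna,,5.98,1
Papilionidae,Eastern Tiger Swallowtail,Papilio glaucus,0.684,0.090,18,215,woodland,,5.98,1
Papilionidae,Spicebush Swallowtail,Papilio troilus,2.554,0.465,8,802,forest,,5.98,1
Pieridae,Checkered White,Pontia protodice,0.071,0.046,47,28,scrub,,7.62,1
Pieridae,Cabbage White,Pieris rapae,1.016,0.252,14,250,open,,4.68,0
Pieridae,Olympia Marble,Euchloe olympia,0.078,0.029,46,31,open,,7.62,1
Pieridae,Clouded Sulphur,Colias philodice,0.304,0.141,28,100,open,***,6.26,0
Pieridae,Orange Sulphur,Colias eurytheme,1.188,0.500,13,530,open,*,8.5,0
Pieridae,Cloudless Sulphur,Phoebis sennae,0.023,0.016,53,10,scrub,,8.5,0
Pieridae,Little Yellow,Eurema lisa,6.382,2.789,5,624,woodland,,1.86,0
Lycaenidae,American Copper,Lycaena phlaeas,0.302,0.252,29,43,open,,2.72,1
Lycaenidae,Bronze Copper,Lycaena hyllus,0.021,0.021,55,3,open,,2.72,1
Lycaenidae,Coral Hairstreak,Satyrium titus,0.236,0.128,32,22,savanna,,1.78,1
Lycaenidae,Edwards' Hairstreak,Satyrium edwardsii,1.538,0.538,12,146,scrub,,1.81,0
Lycaenidae,Banded Hairstreak,Satyrium calanus,0.086,0.048,44,8,scrub,,1.78,1
Lycaenidae,Striped Hairstreak,Satyrium liparops,0.011,0.011,57,1,open,,1.78,1
Lycaenidae,Gray Hairstreak,Strymon melinus,0.227,0.113,34,21,woodland,,1.78,1
Lycaenidae,Eastern Tailed Blue,Everes comyntas,1.879,0.483,9,195,open,,1.97,0
Lycaenidae,Spring Azure,Celastrina ladon,4.265,1.824,6,470,scrub,,2.1,0
Lycaenidae,Karner Blue,Lycaeides melissa samuelis,9.262,4.949,2,1124,savanna,,2.31,0
Nymphalidae,Variegated Fritillary,Euptoieta claudia,0.044,0.026,51,8,open,,3.33,1
Nymphalidae,Great Spangled Fritillary,Speyeria cybele,2.581,0.496,7,559,savanna,,4.13,0
Nymphalidae,Aphrodite Fritillary,Speyeria aphrodite,0.124,0.058,38,22,woodland,,3.33,1
Nymphalidae,Phyciodes spp.,Phyciodes spp.,1.796,0.385,10,249,scrub,,2.64,0
Nymphalidae,Question Mark,Polygonia interrogationis,0.961,0.168,15,48,open,,0.96,1
Nymphalidae,Eastern Comma,Polygonia comma,0.179,0.070,37,9,woodland,,0.96,1
Nymphalidae,Mourning Cloak,Nymphalis antiopa,0.385,0.137,24,19,savanna,,0.96,1
Nymphalidae,American Lady,Vanessa virginiensis,0.661,0.153,19,88,woodland,,2.54,0
Nymphalidae,Red Admiral,Vanessa atalanta,0.828,0.203,17,57,savanna,,1.32,0
Nymphalidae,Common Buckeye,Junonia coenia,0.374,0.100,25,60,open,***,3.07,0
Nymphalidae,Red-spotted Purple,Limenitis arthemis astyanax,0.210,0.042,35,55,scrub,,4.94,0
Nymphalidae,Viceroy,Limenitis archippus,1.700,0.511,11,296,open,,3.32,0
Nymphalidae,Northern Pearly-Eye,Enodia anthedon,0.007,0.007,61,1,forest,,2.81,0
Nymphalidae,Appalachian Brown,Satyrodes appalachia,0.580,0.241,21,86,savanna,,2.81,0
Nymphalidae,Little Wood Satyr,Megisto cymela,14.901,2.621,1,1730,savanna,,2.21,0
Nymphalidae,Common Wood-Nymph,Cercyonis pegala,8.097,1.469,3,765,scrub,,1.8,0
Nymphalidae,Monarch,Danaus plexippus,0.904,0.289,16,341,open,,7.19,0
Hesperiidae,Silver-spotted Skipper,Epargyreus clarus,7.131,1.852,4,408,open,,1.09,0
Hesperiidae,Southern Cloudywing,Thorybes bathyllus,0.240,0.094,31,29,open,,2.31,1
Hesperiidae,Northern Cloudywing,Thorybes pylades,0.083,0.034,45,10,savanna,,2.31,1
Hesperiidae,Hayhurst's Scallopwing,Staphylus hayhurstii,0.008,0.008,58,1,forest,,2.31,1
Hesperiidae,Dreamy Duskywing,Erynnis icelus,0.023,0.016,53,3,open,,2.31,1
Hesperiidae,Sleepy Duskywing,Erynnis brizo,0.550,0.273,22,57,open,,1.98,0
Hesperiidae,Juvenal's Duskywing,Erynnis juvenalis,0.105,0.068,40,13,woodland,,2.31,1
Hesperiidae,Horace's Duskywing,Erynnis horatius,0.340,0.141,26,41,woodland,,2.31,1
Hesperiidae,Mottled Duskywing,Erynnis martialis,0.628,0.582,20,77,scrub,,2.32,0
Hesperiidae,Wild Indigo Duskywing,Erynnis baptisiae,0.230,0.122,33,60,open,,4.94,0
Hesperiidae,European Skipper,Thymelicus lineola,0.039,0.023,52,5,open,,2.45,1
Hesperiidae,Fiery Skipper,Hylephila phyleus,0.049,0.034,49,6,scrub,,2.45,1
Hesperiidae,Leonard's Skipper,Hesperia leonardus,0.196,0.101,36,25,open,,2.45,1
Hesperiidae,Peck's Skipper,Polites peckius,0.089,0.063,43,11,open,,2.45,1
Hesperiidae,Tawny-edged Skipper,Polites themistocles,0.070,0.034,48,9,open,,2.45,1
Hesperiidae,Crossline Skipper,Polites origenes,0.447,0.122,23,123,scrub,,5.25,0
Hesperiidae,Northern Broken Dash,Wallengrenia egeremet,0.311,0.079,27,40,open,,2.45,1
Hesperiidae,Delaware Skipper,Anatrytone logan,0.105,0.051,40,13,open,,2.45,1
Hesperiidae,Byssus Skipper,Problema byssus,0.012,0.012,56,2,open,,2.45,1
Hesperiidae,Hobomok Skipper,Poanes hobomok,0.259,0.082,30,33,savanna,,2.45,1
Hesperiidae,Dun Skipper,Euphyes vestris,0.008,0.008,58,1,woodland,,2.45,1
Hesperiidae,Dusted Skipper,Atrytonopsis hianna,0.099,0.078,42,13,open,,2.45,1
Hesperiidae,Common Roadside-Skipper,Amblyscirtes vialis,0.047,0.026,50,6,open,,2.45,1
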