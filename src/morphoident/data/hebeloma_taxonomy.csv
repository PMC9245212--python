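species,section
Hebeloma adherens,sect. Adherentia
Hebeloma australe,section Australe
Hebeloma album,sect. Denudata subsect. Clepsydroida
Hebeloma ammophilum,sect. Denudata subsect. Clepsydroida
Hebeloma asperosporum,sect. Denudata subsect. Clepsydroida
Hebeloma cavipes,sect. Denudata subsect. Clepsydroida
Hebeloma cinnamomeum,sect. Denudata subsect. Clepsydroida
Hebeloma ingratum,sect. Denudata subsect. Clepsydroida
Hebeloma laetitiae,sect. Denudata subsect. Clepsydroida
Hebeloma limbatum,sect. Denudata subsect. Clepsydroida
Hebeloma matritense,sect. Denudata subsect. Clepsydroida
Hebeloma pseudofragilipes,sect. Denudata subsect. Clepsydroida
Hebeloma sordidulum,sect. Denudata subsect. Clepsydroida
Hebeloma vaccinum,sect. Denudata subsect. Clepsydroida
Hebeloma aanenii,sect. Denudata subsect. Crustuliniformia
Hebeloma alpinum,sect. Denudata subsect. Crustuliniformia
Hebeloma arcticum,sect. Denudata subsect. Crustuliniformia
Hebeloma aurantioumbrinum,sect. Denudata subsect. Crustuliniformia
Hebeloma bellotianum,sect. Denudata subsect. Crustuliniformia
Hebeloma crustuliniforme,sect. Denudata subsect. Crustuliniformia
Hebeloma eburneum,sect. Denudata subsect. Crustuliniformia
Hebeloma geminatum,sect. Denudata subsect. Crustuliniformia
Hebeloma helodes,sect. Denudata subsect. Crustuliniformia
Hebeloma louiseae,sect. Denudata subsect. Crustuliniformia
Hebeloma luteicystidiatum,sect. Denudata subsect. Crustuliniformia
Hebeloma lutense,sect. Denudata subsect. Crustuliniformia
Hebeloma magnicystidiatum,sect. Denudata subsect. Crustuliniformia
Hebeloma minus,sect. Denudata subsect. Crustuliniformia
Hebeloma pallidolabiatum,sect. Denudata subsect. Crustuliniformia
Hebeloma perexiguum,sect. Denudata subsect. Crustuliniformia
Hebeloma pusillum,sect. Denudata subsect. Crustuliniformia
Hebeloma salicicola,sect. Denudata subsect. Crustuliniformia
Hebeloma echinosporum,sect. Denudata subsect. Echinospora
Hebeloma populinum,sect. Denudata subsect. Echinospora
Hebeloma rostratum,sect. Denudata subsect. Echinospora
Hebeloma hiemale,sect. Denudata subsect. Hiemalia
Hebeloma duracinoides,sect. Duracinus
Hebeloma fuscatum,sect. Hebeloma subsect1
Hebeloma grandisporum,sect. Hebeloma subsect1
Hebeloma monticola,sect. Hebeloma subsect1
Hebeloma nigellum,sect. Hebeloma subsect1
Hebeloma paludicola,sect. Hebeloma subsect1
Hebeloma palustre,sect. Hebeloma subsect1
Hebeloma sordescens,sect. Hebeloma subsect1
Hebeloma spetsbergense,sect. Hebeloma subsect1
Hebeloma alpinicola,sect. Hebeloma subsect2
Hebeloma ambustiterranum,sect. Hebeloma subsect2
Hebeloma cistophilum,sect. Hebeloma subsect2
Hebeloma colvinii,sect. Hebeloma subsect2
Hebeloma excedens,sect. Hebeloma subsect2
Hebeloma harperi,sect. Hebeloma subsect2
Hebeloma marginatulum,sect. Hebeloma subsect2
Hebeloma mesophaeum,sect. Hebeloma subsect2
Hebeloma pascuense,sect. Hebeloma subsect2
Hebeloma psammophilum,sect. Hebeloma subsect2
Hebeloma pubescens,sect. Hebeloma subsect2
Hebeloma subtortum,sect. Hebeloma subsect2
Hebeloma velatum,sect. Hebeloma subsect2
Hebeloma islandicum,section Islandica
Hebeloma lacteocoffeatum,section Mediorufa
Hebeloma mediorufum,section Mediorufa
Hebeloma nothofagetorum,section Mediorufa
Hebeloma radicosum,sect. Myxocybe
Hebeloma sagarae,sect. Myxocybe
Hebeloma avellaneum,sect. Naviculospora
Hebeloma catalaunicum,sect. Naviculospora
Hebeloma nanum,sect. Naviculospora
Hebeloma naviculosporum,sect. Naviculospora
Hebeloma subaustrale,sect. Naviculospora
Hebeloma subfastibile,sect. Naviculospora
Hebeloma aminophilum,sect. Porphyrospora
Hebeloma angustilamellatum,sect. Porphyrospora
Hebeloma flavidifolium,sect. Porphyrospora
Hebeloma ifeleletorum,sect. Porphyrospora
Hebeloma indicum,sect. Porphyrospora
Hebeloma lactariolens,sect. Porphyrospora
Hebeloma parvisporum,sect. Porphyrospora
Hebeloma porphyrosporum,sect. Porphyrospora
Hebeloma radicans,sect. Porphyrospora
Hebeloma sarcophyllum,sect. Porphyrospora
Hebeloma victoriense,sect. Porphyrospora
Hebeloma vinosophyllum,sect. Porphyrospora
Hebeloma youngii,sect. Porphyrospora
Hebeloma pseudoamarescens,sect. Pseudoamarescens
Hebeloma fusisporum,sect. Sacchariolentia
Hebeloma ischnostylum,sect. Sacchariolentia
Hebeloma nauseosum,sect. Sacchariolentia
Hebeloma odoratissimum,sect. Sacchariolentia
Hebeloma sacchariolens,sect. Sacchariolentia
Hebeloma anthracophilum,sect. Scabrispora
Hebeloma birrus,sect. Scabrispora
Hebeloma circinans,sect. Scabrispora
Hebeloma cylindrosporum,sect. Scabrispora
Hebeloma danicum,sect. Scabrispora
Hebeloma laterinum,sect. Scabrispora
Hebeloma lindae,sect. Scabrispora
Hebeloma luchuense,sect. Scabrispora
Hebeloma melleum,sect. Scabrispora
Hebeloma pumilum,sect. Scabrispora
Hebeloma radicosoides,sect. Scabrispora
Hebeloma viscidissimum,sect. Scabrispora
Hebeloma bulbiferum,sect. Sinapizantia
Hebeloma sinapizans,sect. Sinapizantia
Hebeloma syrjense,sect. Syrjense
Hebeloma alboerumpens,sect. Theobromina
Hebeloma cohaerens,sect. Theobromina
Hebeloma erumpens,sect. Theobromina
Hebeloma griseopruinatum,sect. Theobromina
Hebeloma parvicystidiatum,sect. Theobromina
Hebeloma plesiocistum,sect. Theobromina
Hebeloma theobrominum,sect. Theobromina
Hebeloma vesterholtii,sect. Theobromina
Hebeloma aestivale,sect. Velutipes
Hebeloma albidulum,sect. Velutipes
Hebeloma celatum,sect. Velutipes
Hebeloma citrisporum,sect. Velutipes
Hebeloma erebium,sect. Velutipes
Hebeloma incarnatulum,sect. Velutipes
Hebeloma leucosarx,sect. Velutipes
Hebeloma neurophyllum,sect. Velutipes
Hebeloma quercetorum,sect. Velutipes
Hebeloma subconcolor,sect. Velutipes
Hebeloma velutipes,sect. Velutipes
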