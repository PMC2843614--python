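# Structural motif annotations per glycan id.
#
# Motif sets are chosen so that the symmetric difference of any two
# annotated glycans reproduces the published "different structures between
# two compared sugars" for the specificity pairs (one published row is
# internally inconsistent under set semantics; see the test suite).
# Core motifs distinguish the type-1 (Gal-beta1,3-GlcNAc) and type-2
# (Gal-beta1,4-GlcNAc) backbone families.
"01": []
"02": []
"03": []
"04": []
"05": []
"06": []
"09": []
"10": []
"11": []
"21": []
"22": []
"23": []
"26": []
"27": []
"28": []
"29": ["α2,3-sialyl(Gal)", "NeuAc"]
"30": ["α2,3-sialyl(Gal)", "NeuGc"]
"31": []
"32": []
"33": ["α2,3-sialyl(Gal)", "ganglio-tetraose"]
"34": []
"38": []
"39": []
"40": []
"41": ["type-2-core"]
"42": ["type-1-core"]
"43": ["type-1-core", "α1,2-fucosyl(Gal)"]
"44": ["type-1-core", "α1,4-fucosyl(GlcNAc)"]
"45": ["type-2-core", "α1,3-fucosyl(GlcNAc)"]
"46": ["type-1-core", "α1,2-fucosyl(Gal)", "α1,4-fucosyl(GlcNAc)"]
"47": ["type-1-core", "α1,2-fucosyl(Gal)", "α1,3-GalNAc(Gal)"]
"48": ["type-1-core", "α1,2-fucosyl(Gal)", "α1,4-fucosyl(GlcNAc)", "α1,3-GalNAc(Gal)"]
"49": []
"50": []
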