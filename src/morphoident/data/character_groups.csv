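group_id,character,role
CG1,latitude,feature
CG1,longitude,feature
CG1,altitude,feature
CG1,spore_ornamentation,feature
CG1,perispore_loosening,feature
CG1,dextrinoidity,feature
CG1,spore_length,feature
CG1,spore_width,feature
CG1,spore_q,feature
CG1,continent,filter_only
CG2,latitude,feature
CG2,longitude,feature
CG2,altitude,feature
CG2,spore_ornamentation,feature
CG2,perispore_loosening,feature
CG2,dextrinoidity,feature
CG2,spore_length,feature
CG2,spore_width,feature
CG2,cheilocystidia_length,feature
CG2,cheilocystidia_shape,feature
CG2,continent,filter_only
CG3,latitude,feature
CG3,longitude,feature
CG3,altitude,feature
CG3,lamellae,feature
CG3,spore_ornamentation,feature
CG3,perispore_loosening,feature
CG3,dextrinoidity,feature
CG3,spore_length,feature
CG3,spore_width,feature
CG3,cheilocystidia_length,feature
CG3,continent,filter_only
CG4,latitude,feature
CG4,longitude,feature
CG4,altitude,feature
CG4,lamellae,feature
CG4,spore_ornamentation,feature
CG4,perispore_loosening,feature
CG4,dextrinoidity,feature
CG4,spore_length,feature
CG4,spore_width,feature
CG4,cheilocystidia_length,feature
CG4,cheilocystidia_shape,feature
CG4,continent,filter_only
CG5,latitude,feature
CG5,longitude,feature
CG5,altitude,feature
CG5,lamellae,feature
CG5,spore_ornamentation,feature
CG5,perispore_loosening,feature
CG5,dextrinoidity,feature
CG5,spore_length,feature
CG5,spore_width,feature
CG5,cheilocystidia_length,feature
CG5,cheilocystidia_shape,feature
CG5,spore_q,feature
CG5,cheilocystidia_ab,feature
CG5,cheilocystidia_bm,feature
CG5,continent,filter_only
CG6,latitude,feature
CG6,longitude,feature
CG6,altitude,feature
CG6,lamellae,feature
CG6,spore_ornamentation,feature
CG6,perispore_loosening,feature
CG6,dextrinoidity,feature
CG6,spore_length,feature
CG6,spore_width,feature
CG6,cheilocystidia_length,feature
CG6,cheilocystidia_shape,feature
CG6,spore_q,feature
CG6,cheilocystidia_ab,feature
CG6,cheilocystidia_bm,feature
CG6,cheilocystidia_apex_width,feature
CG6,continent,filter_only
CG7,latitude,feature
CG7,longitude,feature
CG7,altitude,feature
CG7,lamellae,feature
CG7,spore_ornamentation,feature
CG7,perispore_loosening,feature
CG7,dextrinoidity,feature
CG7,spore_length,feature
CG7,spore_width,feature
CG7,cheilocystidia_length,feature
CG7,cheilocystidia_shape,feature
CG7,spore_q,feature
CG7,cheilocystidia_ab,feature
CG7,cheilocystidia_bm,feature
CG7,cheilocystidia_apex_width,feature
CG7,cheilocystidia_am,feature
CG7,continent,filter_only
CG8,latitude,feature
CG8,longitude,feature
CG8,altitude,feature
CG8,lamellae,feature
CG8,spore_ornamentation,feature
CG8,perispore_loosening,feature
CG8,dextrinoidity,feature
CG8,spore_length,feature
CG8,spore_width,feature
CG8,cheilocystidia_length,feature
CG8,cheilocystidia_shape,feature
CG8,spore_q,feature
CG8,cheilocystidia_ab,feature
CG8,cheilocystidia_bm,feature
CG8,cheilocystidia_apex_width,feature
CG8,cheilocystidia_am,feature
CG8,basidia_q,feature
CG8,continent,filter_only
CG9,latitude,feature
CG9,longitude,feature
CG9,altitude,feature
CG9,lamellae,feature
CG9,spore_ornamentation,feature
CG9,perispore_loosening,feature
CG9,dextrinoidity,feature
CG9,spore_length,feature
CG9,spore_width,feature
CG9,cheilocystidia_length,feature
CG9,cheilocystidia_shape,feature
CG9,cheilocystidia_ab,feature
CG9,cheilocystidia_bm,feature
CG9,cheilocystidia_apex_width,feature
CG9,basidia_q,feature
CG9,plant_family,feature
CG9,continent,filter_only
CGA,dextrinoidity,feature
CGA,lamellae,feature
CGA,cheilocystidia_length,feature
CGA,cheilocystidia_am,feature
CGA,continent,filter_only
CGB,dextrinoidity,feature
CGB,lamellae,feature
CGB,basidia_q,feature
CGB,cheilocystidia_am,feature
CGB,continent,filter_only
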