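{
  "_comment": "Synthetic reconstruction of the 18-category journal-title keyword map. Category names and their priority order follow the published methods; the keyword lists are this package's own reconstruction built from the printed examples plus common journal-title vocabulary, NOT the authors' supplementary mapping. Matching is lowercase substring containment, first category wins.",
  "categories": {
    "oncology": ["cancer", "oncol", "oncogene", "tumor", "tumour", "carcinogen", "leukemia", "lymphoma", "neoplas"],
    "plant biology": ["plant", "botan", "phytochem", "crop", "agronom", "horticult", "photosynth"],
    "nephrology": ["nephrol", "kidney", "renal", "dialysis"],
    "endocrinology": ["endocrin", "diabet", "thyroid", "hormon", "pituitar"],
    "microbiology": ["microbiol", "bacteriol", "yeast", "microbiome", "virol", "mycol", "microorganism"],
    "analytical chemistry": ["analytical chem", "analyt", "chromatogr", "spectrometr", "spectrosc", "electrophor", "talanta"],
    "pharmacology": ["pharmac", "drug", "therapeut", "xenobiotic"],
    "neuroscience": ["neuro", "brain", "psychiatr", "cortex", "cognit"],
    "food science and nutrition": ["food", "nutri", "dairy", "cereal", "appetite"],
    "toxicology": ["toxicol", "toxic", "poison"],
    "environmental science": ["environ", "ecolog", "pollut", "chemosphere", "soil", "atmospher"],
    "animal science": ["animal", "veterinar", "livestock", "poultry", "zoolog", "aquacult", "fish"],
    "sports science and medicine": ["sport", "exercise", "athlet", "kinesiol"],
    "epidemiology and public health": ["epidemiol", "public health", "preventive medicine", "population health"],
    "developmental biology": ["developmental biol", "development", "embryo", "placenta"],
    "aging and gerontology": ["aging", "ageing", "gerontol", "geriatr", "longevity"],
    "immunology and vaccine research": ["immun", "vaccin", "allerg", "inflamm"],
    "computational biology": ["computational", "bioinformat", "in silico", "systems biology", "machine learning"]
  }
}
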