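{
  "modality": "anterior",
  "nodes": [
    {"id": "anterior_segment", "name": "Anterior segment", "level": 0, "parent": null},
    {"id": "ocular_surface", "name": "Ocular surface disease", "level": 1, "parent": "anterior_segment"},
    {"id": "ocular_neoplasm", "name": "Ocular neoplasm", "level": 1, "parent": "anterior_segment"},
    {"id": "cataract", "name": "Cataract", "level": 1, "parent": "anterior_segment"},
    {"id": "normal_surface", "name": "Normal surface", "level": 1, "parent": "anterior_segment"},
    {"id": "conjunctivitis", "name": "Conjunctivitis", "level": 2, "parent": "ocular_surface"},
    {"id": "cornea_degeneration", "name": "Corneal degeneration", "level": 2, "parent": "ocular_surface"},
    {"id": "cornea_infectious", "name": "Corneal infectious disease", "level": 2, "parent": "ocular_surface"},
    {"id": "cornea_non_infectious", "name": "Corneal non-infectious disease", "level": 2, "parent": "ocular_surface"},
    {"id": "scleritis", "name": "Scleritis", "level": 2, "parent": "ocular_surface"},
    {"id": "intraocular_neoplasma", "name": "Intraocular neoplasma", "level": 2, "parent": "ocular_neoplasm"},
    {"id": "ocular_surface_neoplasm", "name": "Ocular surface neoplasm", "level": 2, "parent": "ocular_neoplasm"},
    {"id": "cataract_l2", "name": "Cataract (subclass)", "level": 2, "parent": "cataract"},
    {"id": "normal_surface_l2", "name": "Normal surface (subclass)", "level": 2, "parent": "normal_surface"}
  ],
  "class_order": {
    "1": ["ocular_surface", "ocular_neoplasm", "cataract", "normal_surface"],
    "2": ["conjunctivitis", "cornea_degeneration", "cornea_infectious", "cornea_non_infectious", "scleritis", "intraocular_neoplasma", "ocular_surface_neoplasm", "cataract_l2", "normal_surface_l2"]
  }
}
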