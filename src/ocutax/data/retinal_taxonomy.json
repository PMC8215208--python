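{
  "modality": "retinal",
  "nodes": [
    {"id": "retinal_fundus", "name": "Retinal fundus", "level": 0, "parent": null},
    {"id": "vitreoretinal_disease", "name": "Vitreoretinal disease", "level": 1, "parent": "retinal_fundus"},
    {"id": "glaucoma", "name": "Glaucoma", "level": 1, "parent": "retinal_fundus"},
    {"id": "normal_fundus", "name": "Normal fundus", "level": 1, "parent": "retinal_fundus"},
    {"id": "macular_disease", "name": "Macular disease", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "optic_nerve_disease", "name": "Optic nerve disease", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "refractive_error", "name": "Refractive error", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "retinal_degeneration", "name": "Retinal degeneration", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "retinal_detachment", "name": "Retinal detachment", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "retinal_vascular_disease", "name": "Retinal vascular disease", "level": 2, "parent": "vitreoretinal_disease"},
    {"id": "glaucoma_l2", "name": "Glaucoma (subclass)", "level": 2, "parent": "glaucoma"},
    {"id": "normal_fundus_l2", "name": "Normal fundus (subclass)", "level": 2, "parent": "normal_fundus"}
  ],
  "class_order": {
    "1": ["vitreoretinal_disease", "glaucoma", "normal_fundus"],
    "2": ["macular_disease", "optic_nerve_disease", "refractive_error", "retinal_degeneration", "retinal_detachment", "retinal_vascular_disease", "glaucoma_l2", "normal_fundus_l2"]
  }
}
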