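{
  "modality": "synthetic",
  "nodes": [
    {"id": "desk_root", "name": "Synthetic desk fixture", "level": 0, "parent": null},
    {"id": "warm_group", "name": "Warm-background group", "level": 1, "parent": "desk_root"},
    {"id": "cool_group", "name": "Cool-background group", "level": 1, "parent": "desk_root"},
    {"id": "warm_vertical", "name": "Warm group, vertical-stripe lesion", "level": 2, "parent": "warm_group"},
    {"id": "warm_horizontal", "name": "Warm group, horizontal-stripe lesion", "level": 2, "parent": "warm_group"},
    {"id": "cool_vertical", "name": "Cool group, vertical-stripe lesion", "level": 2, "parent": "cool_group"},
    {"id": "cool_horizontal", "name": "Cool group, horizontal-stripe lesion", "level": 2, "parent": "cool_group"}
  ],
  "class_order": {
    "1": ["warm_group", "cool_group"],
    "2": ["warm_vertical", "warm_horizontal", "cool_vertical", "cool_horizontal"]
  }
}
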