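{
 "description": "Variable inventory for the community-sports-park social-interaction analysis: 12 spatial, 2 activity, 3 individual-difference and 2 social-interaction variables. Category systems follow the published conditional-probability tables; bins are half-open [lower, upper), last bin closed, null = unbounded.",
 "variables": [
  {"name": "accessibility", "role": "spatial", "states": ["near", "medium", "far"], "bin_edges": [0, 25, 50, null], "unit": "m"},
  {"name": "space_enclosure", "role": "spatial", "states": ["low", "medium", "high"], "bin_edges": [0, 0.34, 0.67, 1.0], "unit": "ratio"},
  {"name": "visual_obstacles", "role": "spatial", "states": ["0-10", "11-20", "21-27", "28-32"], "bin_edges": [0, 11, 21, 28, 32], "unit": "%"},
  {"name": "path_width", "role": "spatial", "states": ["narrow", "medium", "wide"], "bin_edges": [0, 1.5, 2.1, 3.5], "unit": "m"},
  {"name": "seats_density", "role": "spatial", "states": ["0-5", "6-10", "11-15", "16-25"], "bin_edges": [0, 6, 11, 16, 25], "unit": "m per 100 m"},
  {"name": "fitness_equipment", "role": "spatial", "states": ["few", "medium", "many"], "bin_edges": [0, 6, 11, null], "unit": "pcs"},
  {"name": "childrens_play_equipment", "role": "spatial", "states": ["no", "some", "many"], "bin_edges": [0, 1, 3, null], "unit": "pcs"},
  {"name": "sports_court", "role": "spatial", "states": ["few", "medium", "many"], "bin_edges": [1, 2, 3, null], "unit": "pcs"},
  {"name": "shrub_area", "role": "spatial", "states": ["small", "medium", "large"], "bin_edges": [0, 50, 150, null], "unit": "m2"},
  {"name": "tree_cover", "role": "spatial", "states": ["low", "medium", "high"], "bin_edges": [0, 0.2, 0.4, 1.0], "unit": "ratio"},
  {"name": "green_view_index", "role": "spatial", "states": ["low", "medium", "high"], "bin_edges": [0, 15, 30, 100], "unit": "%"},
  {"name": "vegetation_diversity", "role": "spatial", "states": ["0.2-0.5", "0.6-0.8", "0.9-1.2", "1.3-1.8", "1.8-2.1", "2.2-2.3"], "bin_edges": [0.2, 0.6, 0.9, 1.3, 1.8, 2.2, 2.3], "unit": "nats"},
  {"name": "physical_activity", "role": "activity", "states": ["yes", "no"], "bin_edges": null, "unit": null},
  {"name": "leisure_activity", "role": "activity", "states": ["yes", "no"], "bin_edges": null, "unit": null},
  {"name": "age", "role": "individual", "states": ["<15", "15-25", "26-35", "36-45", "46-55", "56-65", ">65"], "bin_edges": [0, 15, 26, 36, 46, 56, 66, null], "unit": "years"},
  {"name": "gender", "role": "individual", "states": ["male", "female"], "bin_edges": null, "unit": null},
  {"name": "social_relationship", "role": "individual", "states": ["alone", "general_neighborhood", "familiar_neighborhood", "family_friends"], "bin_edges": null, "unit": null},
  {"name": "crowds_congregate", "role": "interaction", "states": ["very_low", "low", "medium", "high", "very_high"], "bin_edges": null, "unit": null},
  {"name": "engagement", "role": "interaction", "states": ["low", "medium", "high"], "bin_edges": null, "unit": null}
 ]
}
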