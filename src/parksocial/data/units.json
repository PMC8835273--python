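{
 "description": "Spatial study units of the three Chongqing community sports parks. Subtype membership follows the published unit inventory; park assignment is a synthetic convention (contiguous unit-number blocks by park size) because the source map is not machine-readable.",
 "questionnaires_by_park": {
  "Dashuijing": 124,
  "Huilongwan": 133,
  "Danlong": 96
 },
 "units": [
  {
   "unit_id": 1,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 2,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 3,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "basketball_court"
  },
  {
   "unit_id": 4,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "badminton_court"
  },
  {
   "unit_id": 5,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "square_dancing_venue"
  },
  {
   "unit_id": 6,
   "park": "Dashuijing",
   "space_type": "path",
   "subtype": "plastic_runway"
  },
  {
   "unit_id": 7,
   "park": "Dashuijing",
   "space_type": "path",
   "subtype": "recreational_trail"
  },
  {
   "unit_id": 8,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 9,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "childrens_playground"
  },
  {
   "unit_id": 10,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 11,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "childrens_playground"
  },
  {
   "unit_id": 12,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 13,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "badminton_court"
  },
  {
   "unit_id": 14,
   "park": "Dashuijing",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 15,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 16,
   "park": "Dashuijing",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 17,
   "park": "Huilongwan",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 18,
   "park": "Huilongwan",
   "space_type": "sports_court",
   "subtype": "badminton_court"
  },
  {
   "unit_id": 19,
   "park": "Huilongwan",
   "space_type": "sports_court",
   "subtype": "basketball_court"
  },
  {
   "unit_id": 20,
   "park": "Huilongwan",
   "space_type": "path",
   "subtype": "plastic_runway"
  },
  {
   "unit_id": 21,
   "park": "Huilongwan",
   "space_type": "path",
   "subtype": "plastic_runway"
  },
  {
   "unit_id": 22,
   "park": "Huilongwan",
   "space_type": "path",
   "subtype": "recreational_trail"
  },
  {
   "unit_id": 23,
   "park": "Huilongwan",
   "space_type": "path",
   "subtype": "recreational_trail"
  },
  {
   "unit_id": 24,
   "park": "Huilongwan",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 25,
   "park": "Huilongwan",
   "space_type": "fitness_equipment",
   "subtype": "equipment_space"
  },
  {
   "unit_id": 26,
   "park": "Huilongwan",
   "space_type": "fitness_equipment",
   "subtype": "childrens_playground"
  },
  {
   "unit_id": 27,
   "park": "Huilongwan",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 28,
   "park": "Huilongwan",
   "space_type": "sports_court",
   "subtype": "table_tennis_court"
  },
  {
   "unit_id": 29,
   "park": "Danlong",
   "space_type": "sports_court",
   "subtype": "basketball_court"
  },
  {
   "unit_id": 30,
   "park": "Danlong",
   "space_type": "sports_court",
   "subtype": "badminton_court"
  },
  {
   "unit_id": 31,
   "park": "Danlong",
   "space_type": "path",
   "subtype": "plastic_runway"
  },
  {
   "unit_id": 32,
   "park": "Danlong",
   "space_type": "path",
   "subtype": "plastic_runway"
  },
  {
   "unit_id": 33,
   "park": "Danlong",
   "space_type": "path",
   "subtype": "recreational_trail"
  },
  {
   "unit_id": 34,
   "park": "Danlong",
   "space_type": "path",
   "subtype": "recreational_trail"
  },
  {
   "unit_id": 35,
   "park": "Danlong",
   "space_type": "path",
   "subtype": "recreational_trail"
  }
 ]
}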