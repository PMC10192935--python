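# Mother Jones mass-shootings database export dialect.
# "location" holds "City, State" combined; split on the last comma.
source: MJ
delimiter: ","
encoding: utf-8
date_format: "%m/%d/%Y"
victim_count_basis: EXCLUDES_PERP
victim_level: false
column_map:
  "case": source_id
  "location": city_state
  "date": date
  "shooter": shooter_names
  "shooters": n_shooters
  "fatalities": killed_excl_perp
  "injured": injured_excl_perp
  "shooter_outcome": perp_died
  "motive_category": motive
  "location_type": location_type
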