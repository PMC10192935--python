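# FBI Active Shooter Report export dialect (tabular export, one incident/row).
source: ASR
delimiter: ","
encoding: utf-8
date_format: "%m/%d/%Y"
victim_count_basis: EXCLUDES_PERP
victim_level: false
column_map:
  "Incident #": source_id
  "Date": date
  "State": state
  "City": city
  "Shooter": shooter_names
  "Number of Shooters": n_shooters
  "Killed": killed_excl_perp
  "Wounded": injured_excl_perp
  "Shooter Outcome": perp_died
  "Circumstances": motive
  "Location": location_type
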