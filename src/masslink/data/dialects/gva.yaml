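# Gun Violence Archive export dialect.  GVA exports no shooter names.
source: GVA
delimiter: ","
encoding: utf-8
date_format: "%B %d, %Y"
victim_count_basis: EXCLUDES_PERP
victim_level: false
column_map:
  "Incident ID": source_id
  "Incident Date": date
  "State": state
  "City Or County": city
  "# Killed": killed_excl_perp
  "# Injured": injured_excl_perp
  "# Subjects-Suspects": n_shooters
  "Suspect Outcome": perp_died
  "Incident Characteristics": motive
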