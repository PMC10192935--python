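# FBI Supplementary Homicide Report export dialect.
# SHR is victim-level: one row per decedent.  Rows are grouped into incidents
# by (agency, incident number, date); the fatality count of an incident is its
# number of victim rows.  SHR reports no injury counts.
source: SHR
delimiter: ","
encoding: utf-8
date_format: "%m/%d/%Y"
victim_count_basis: EXCLUDES_PERP
victim_level: true
group_keys: [agency, incident_num]
column_map:
  "Agency": agency
  "Incident": incident_num
  "Date": date
  "State": state
  "City": city
  "Offender Name": shooter_names
  "Offender Count": n_shooters
  "Weapon": weapon
  "Circumstance": motive
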