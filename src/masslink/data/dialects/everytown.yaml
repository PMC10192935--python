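# Everytown for Gun Safety export dialect.
# This export counts the shooter among the dead; the reader subtracts one when
# the shooter is recorded as killed, and flags the count unknown otherwise.
source: EVERYTOWN
delimiter: ","
encoding: utf-8
date_format: "%Y-%m-%d"
victim_count_basis: INCLUDES_PERP
victim_level: false
column_map:
  "Incident ID": source_id
  "Date": date
  "State": state
  "City": city
  "Shooter Names": shooter_names
  "Number of Shooters": n_shooters
  "People Killed": killed_excl_perp
  "People Wounded": injured_excl_perp
  "Shooter Killed": perp_died
  "Circumstance": motive
  "Location Type": location_type
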