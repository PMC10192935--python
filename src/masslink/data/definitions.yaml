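# Inclusion criteria for the five mass-shooting databases, 2013-2020 window.
#
# count_basis: FATALITIES counts killed only; CASUALTIES counts killed+injured.
# min_count 0 means the database applies no victim-count threshold.
# All thresholds exclude the perpetrator(s).
# fail_open lists rule families where an unknown field does NOT exclude the
# record (motive/location exclusions apply only to *known* motives/locations);
# count and shooter rules fail closed by default.
SHR:
  count_basis: FATALITIES
  min_count: 4
  perp_excluded: true
  min_shooters: 1
  max_shooters: 1
  shooter_must_be_known: false
  excluded_motives: []
  location_restriction: NONE
ASR:
  count_basis: FATALITIES
  min_count: 0
  perp_excluded: true
  shooter_must_be_known: false
  excluded_motives: [GANG, DRUG, FAMILY_IPV]
  location_restriction: NONE
MJ:
  count_basis: FATALITIES
  min_count: 3
  perp_excluded: true
  min_shooters: 1
  max_shooters: 1
  shooter_must_be_known: true
  excluded_motives: [ROBBERY, GANG, FAMILY_IPV]
  location_restriction: NONE
EVERYTOWN:
  count_basis: FATALITIES
  min_count: 4
  perp_excluded: true
  shooter_must_be_known: false
  excluded_motives: []
  location_restriction: NONE
GVA:
  count_basis: CASUALTIES
  min_count: 4
  perp_excluded: true
  min_shooters: 1
  max_shooters: 2
  shooter_must_be_known: false
  excluded_motives: []
  location_restriction: NONE
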