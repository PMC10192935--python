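"""Published per-database counts for the 2013–2020 comparison.

The five databases are live and cannot be re-snapshotted reproducibly, but
their published per-source tallies — total incidents listed, and incidents
surviving the conservative >=4-fatality definition — are fixed numbers whose
internal arithmetic (the filter ledger: excluded = total - surviving) the
package recomputes.  Overlap headline counts from the same comparison are
included for context.
"""

from __future__ import annotations

from .records import Source

#: Total incidents each database lists for 2013–2020.
TOTAL_INCIDENTS: dict[Source, int] = {
    Source.SHR: 210,
    Source.ASR: 208,
    Source.MJ: 57,
    Source.EVERYTOWN: 157,
    Source.GVA: 2950,
}

#: Incidents per database surviving the >=4-fatality threshold.
SURVIVING_AT_4_FATALITIES: dict[Source, int] = {
    Source.SHR: 210,
    Source.ASR: 42,
    Source.MJ: 38,
    Source.EVERYTOWN: 157,
    Source.GVA: 211,
}

#: Headline overlap counts across the five databases, 2013–2020.
UNION_INCIDENTS = 3155            # discrete incidents in at least one database
FULL_INTERSECTION = 25            # incidents present in all five
UNION_EXCL_GVA = 428              # union of the four non-GVA databases
FULL_INTERSECTION_EXCL_GVA = 25
FULL_INTERSECTION_EXCL_ASR = 26   # overlap of the four non-ASR databases
UNION_AT_4_FATALITIES = 307       # union after the >=4-fatality re-filter
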