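"""Derive flowering onsets from a volunteer's "Yes"/"No" status reports.

A volunteer visits a plant every few days and reports whether flowers are
visible.  The onset is the day of the first "Yes" in each bloom episode; its
uncertainty is the gap back to the last "No" before it.
"""

from phenofence import derive_onsets, simulate_status_series

# weekly visits around a true onset at DOY 100, with a second autumn bloom
reports = simulate_status_series(
    onset_doy=100, visit_interval_days=7, first_visit=60, second_onset=250
)
print("visit log (doy, status):")
print("  " + ", ".join(f"({r.doy},{r.status[0].upper()})" for r in reports))

onsets, multiple = derive_onsets(reports)
for doy, unc in onsets:
    print(f"onset at DOY {doy}, uncertainty {unc} days")
print("multiple onsets this year:", multiple)
# The first onset is reported at the first "Yes" visit (DOY 102), 7 days
# after the last "No": weekly visits bound the onset uncertainty at 7 days.
# The autumn episode makes this a multiple-onset plant-year, which the
# screening workflow carries as a flag.
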