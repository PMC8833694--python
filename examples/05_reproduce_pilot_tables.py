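"""Reproduce the pilot study's score and performance tables from the fixture.

The embedded fixture holds only the published per-subject 0/1 scores and
pathology outcomes (no raw data needed).  The replica matches the
reported table cell-for-cell except one confidence bound, flagged below.
"""

from lnscore.fixtures import compare_with_reported, pilot_report, pilot_scorecards

for card in pilot_scorecards():
    print(f"subject {card.subject_id}: sum {card.sum_score}/{card.available_count}"
          f" = {card.sum_percent_display}%")

print()
print(pilot_report().to_string(index=False))

for d in compare_with_reported():
    print(f"\nflagged cell: {d['variable']} {d['metric']} -- computed "
          f"{d['computed']!r} vs reported {d['reported']!r} (the exact upper "
          "bound for 3/4 rounds to 99; suspected typo in the original table)")
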