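"""Re-derive every published figure from the printed confusion matrices.

The packaged fixtures hold the study's row-percent confusion matrices.
Converting them back to integer counts at 27 test trials per environment
and applying the metric definitions must reproduce each printed accuracy,
sensitivity and specificity; one uphill-specificity cell is internally
inconsistent in print and is flagged rather than failed.
"""

from gaitenv import check_tables

for r in check_tables():
    flag = {"pass": "ok", "fail": "MISMATCH",
            "known_discrepancy": "known discrepancy"}[r.status]
    print(f"{r.name:24s} computed {r.computed:6.1f} "
          f"published {r.published:6.1f}  [{flag}]")
    if r.note:
        print(f"    note: {r.note}")
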