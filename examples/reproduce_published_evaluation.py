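"""Reproduce the published model-evaluation headline numbers.

Chains the packaged dustiness and paired-observation tables through the
ratio statistics, benchmark-band classification, MAE computation,
corrected-H rescaling and LEV sweep, and prints every recomputed value
next to its published counterpart.
"""

from dustbox import load_fixtures, render_report, reproduce_published

bundle = load_fixtures()
results = reproduce_published(bundle)

for row in results.itertuples():
    where = "/".join(
        str(v) for v in (row.fraction, row.model, row.di_method) if v is not None
    )
    label = f"{row.quantity} [{where}]" if where else row.quantity
    flag = "ok" if row.passed else "MISMATCH"
    print(f"{label:58s} computed {row.computed:10.3f}  published "
          f"{row.published:8.2f}  {flag}")

print(f"\n{int(results.passed.sum())}/{len(results)} checks passed")
written = render_report(results, "report", plots=False, bundle=bundle)
print("report written to:", ", ".join(str(p) for p in written))
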