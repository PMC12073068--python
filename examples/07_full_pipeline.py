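"""One-call pipeline: simulate a cohort, analyse it end to end, and write
every table plus a JSON report.

Equivalent to `retinagaze run-all --participants 6 --images 8 --seed 7
--out scratch/demo_run` from the shell.
"""

from retinagaze import RunConfig, run_pipeline

report = run_pipeline(
    RunConfig(n_participants=6, n_images=8, seed=7), "scratch/demo_run"
)

print("accuracies:", {k: round(v, 3) for k, v in report["accuracy"].items()})
print(f"alpha (grades, ordinal): {report['alpha_grade']:.3f}")
print("zoom-time fractions:",
      {f"{z:.2f}x": round(f, 2) for z, f in report["zoom_fractions"].items()})
top = report["patterns"]["correct"]["top"][0]
print(f"top correct exemplar: {top.exemplar} (size {top.size})")
print("tables written to scratch/demo_run/ (responses, strings, metrics, report.json)")
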