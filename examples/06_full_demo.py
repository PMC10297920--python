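"""Run every pipeline stage against synthetic ground truth in one call.

Equivalent to `ovimyo demo --seed 7`: generates images and counts, runs
morphometry, DE, modules, trends and bias calls, and verifies each stage's
recovery/calibration property.
"""

from ovimyo.pipeline import run_demo

report = run_demo(seed=7)
for name, check in report["checks"].items():
    status = "ok " if check["pass"] else "FAIL"
    value = check["value"]
    shown = f"{value:.4g}" if isinstance(value, float) else value
    print(f"[{status}] {name}: {shown}")
print("overall:", "PASSED" if report["passed"] else "FAILED")
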