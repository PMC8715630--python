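"""Assemble a results grid and render it as markdown.

Each cell is one cross-validated (measure, device, model) correlation with
its qualitative strength label (very weak / weak / moderate / strong).
"""

import warnings

from robokin import build_report, interpret_r, patientwise_cv, render_markdown, simulate_feature_cohort

warnings.simplefilter("ignore")
cells = []
for seed, measure in ((1, "FMA-UE 0-66"), (2, "WMFT")):
    df = simulate_feature_cohort(40, 3, 0.85, seed=seed, target="wmft")
    for kind, label in (("linear", "linear"), ("mlp", "nonlinear")):
        cv = patientwise_cv(df, ["x"], "wmft", kind=kind, k=4, seed=seed)
        cells.append((measure, "shoulder_elbow", label, cv))

report = build_report(cells, provenance={"seeds": "1,2"})
print(render_markdown(report))
print(f"(interpret_r(0.82) = {interpret_r(0.82)!r}, interpret_r(0.45) = {interpret_r(0.45)!r})")
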