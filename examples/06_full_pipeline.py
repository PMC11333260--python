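"""End-to-end pipeline run on the bundled synthetic scenario.

Executes every stage in study order (instrument construction with
colocalization, positive control, outcome MR, metabolite screen,
mediation, meta-analysis, phenome screen) and prints the report skeleton.
Rerunning with the same config reproduces the report byte for byte.
"""

import drugtarget_mr as dm

report = dm.run_pipeline({"seed": 5, "estimators": {"n_boot": 200, "n_sim": 500}})

print("stages executed:", ", ".join(report["stages"]))
inst = report["stages"]["instruments"]
print(f"colocalization PP.H4 = {inst['colocalization']['PP.H4']:.3f}")
print(f"instruments after clumping: {inst['counts']['after_clumping']}")

ivw = next(e for e in report["stages"]["outcome_mr"]["estimates"] if e["method"] == "ivw_mre")
print(f"outcome MR (IVW): beta = {ivw['beta']:.3f} (truth "
      f"{report['stages']['outcome_mr']['truth']['theta_total']:.3f})")
med = report["stages"]["mediation"]
print(f"proportion mediated = {100 * med['result']['proportion_mvmr']:.1f}% "
      f"(truth {100 * med['true_proportion']:.1f}%)")
print(f"phenome screen: {report['stages']['phewas']['n_significant']} significant "
      f"of {report['stages']['phewas']['n_tests']}")
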