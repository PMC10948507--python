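"""Predict salt tolerance from seven traits with the bundled reference model.

Evaluates the published seven-trait linear model on its verification panel
and compares predicted Y values with the full-assay D values.
"""

import salicore as sc

model = sc.reference_model()
panel = sc.load_verification_panel()

print("genotype  grade   D (full assay)   Y (7-trait model)")
for _, row in panel.iterrows():
    y = sc.predict_tolerance(model, row.to_dict())["Y_rounded"]
    print(f"{row['genotype_id']:>8}  {row['grade']:>4}   {row['D']:.4f}           {y:.4f}")

print("\nY approximates the 14-trait comprehensive score D from only seven traits")
print("(SNC, RNIL, RWC, RGR, RKC, Sen, RNC); close D-Y agreement means a genotype")
print("can be graded without the full assay.")
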