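"""Protonation fractions and driver/stabilizer labels for hASIC1a.

Uses the published pKa triple of the top-ranked acidic-pocket glutamate
(E238: 0.58 / 6.24 / 7.81 in the closed / open / desensitized models) to
rebuild its Table-3-style protonation-fraction row, then classifies the
whole published table into drivers and stabilizers of activation with
the |Δf(prot)| >= 0.15 rule.
"""
from membpka.sensor_analysis import (
    classify_driver_stabilizer,
    fprot_table,
    load_published_fprot_table,
)

row = fprot_table({"Glu238": 0.58}, {"Glu238": 6.24}, {"Glu238": 7.81}).iloc[0]
print("Glu238 protonation fractions "
      "(closed 7.4 | start/end activation 6.0 | start/end SSD 6.8):")
print("  ", " ".join(
    f"{row[c + '_2dp']:.2f}" for c in (
        "f_closed", "f_start_activation", "f_end_activation",
        "f_start_ssd", "f_end_ssd")
))
# 0.00 0.00 0.63 0.00 0.91: deprotonated while closed, mostly protonated
# once the open (0.63) or desensitized (0.91) conformation is reached —
# a stabilizer of both transitions rather than a driver.

published = load_published_fprot_table()
labels = classify_driver_stabilizer(published, "activation", threshold=0.15)
drivers = labels.loc[labels["driver"], "site"].tolist()
stabilizers = labels.loc[labels["stabilizer"], "site"].tolist()
print(f"\nactivation drivers (|Δf| ≥ 0.15 at acidification): {drivers}")
print(f"activation stabilizers: {stabilizers}")
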