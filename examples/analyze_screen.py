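"""Classify a Match/Mismatch viability screen.

Simulates a 7-pair screen in the shape of a real essential-gene validation:
one gene with a genuine on-target viability effect, one whose phenotype is
off-target (the Mismatch control also kills cells), five inert. Knockdown
efficiencies come from the qPCR Ct tables via 2^-ddCt with GAPDH
normalization; calls use the 60%/50-point screening criteria and the 0.80
viability threshold.
"""

from sirnakit import analyze_screen, gen_assay_tables, screen_report

ct, viability, manifest = gen_assay_tables(seed=11)
records = analyze_screen(ct, viability)

report = screen_report(records)
print(report.round(3).to_string(index=False))
print()
counts = report.attrs["call_counts"]
print("call counts:", ", ".join(f"{k}={v}" for k, v in counts.items()))
print("planted truth:", manifest["expected_calls"])
print()
print(
    "kd_* are knockdown efficiencies (% vs the untreated blank control); "
    "viability_* are ratios to the blank. A pair passes the screen when the "
    "Match knocks down >60% and beats the Mismatch by >=50 points. A "
    "sub-0.80 Mismatch viability flags the phenotype as off-target; "
    "otherwise sub-0.80 Match viability calls the gene essential."
)
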