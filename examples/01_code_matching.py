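"""Match ICD-9-CM diagnosis codes against the 12-condition codebook.

The packaged codebook transcribes the published condition code lists:
wildcarded codes ("250.xx"), plain codes with family-level intent ("496"),
and ranges with excluded gaps ("430-437.1, 437.3-438.xx" leaves out 437.2,
which belongs to hypertension)."""

from claims_lookback import ConditionCodebook, normalize_code

codebook = ConditionCodebook.builtin()

for raw in ["250.00", "V42.7", "437.2", "437.1", "438.91", "496", "4961"]:
    code = normalize_code(raw)
    hits = codebook.conditions_matching(code)
    print(f"{raw:>8} -> {code:<6} matches: {', '.join(hits) if hits else '(none)'}")

# A code can belong to several conditions: hypertensive renal disease
print("\n403.01 ->", ", ".join(codebook.conditions_matching(normalize_code("403.01"))))
print(
    "\nEach line shows a claim code, its normalized (dotless) form, and the\n"
    "conditions whose published code lists cover it; 437.2 lands in\n"
    "hypertension, not cerebrovascular disease, exactly as the lists print it."
)
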