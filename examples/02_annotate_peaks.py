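"""Annotate observed peaks by accurate mass and MS/MS neutral losses.

Reproduces the two classic worked annotations: a lysoPC(20:4) sodium
adduct confirmed by its trimethylamine/phosphocholine losses, and ATP
confirmed by its adenine-loss fragment.
"""

from msimet import annotate_ms1, annotate_msms, consolidate, load_compound_db
from msimet.annotation import load_fragmentation_rules

db = load_compound_db()
rules = load_fragmentation_rules()

for observed, mode, fragments in [
    (566.32166, "positive", [507.24815, 383.25558]),
    (505.98833, "negative", [272.95698]),
]:
    hits = annotate_ms1(observed, mode, db, tolerance_ppm=2.0)
    matches = annotate_msms(observed, fragments, mode, rules)
    final = consolidate(hits, matches)
    print(f"m/z {observed} ({mode} mode)")
    print(f"  -> {final.name} {final.adduct}, theoretical {final.theoretical_mz:.6f}, "
          f"error {final.error_ppm:+.2f} ppm, evidence {final.evidence}")
    for m in matches:
        kind = "loss" if m.rule.kind == "neutral_loss" else "fragment"
        print(f"     {kind} {m.rule.formula.hill()} observed {m.observed_value:.5f} "
              f"({m.error.ppb:+.0f} ppb)")
    print()

print("MS1 matching finds every candidate within +/-2 ppm; the class-specific")
print("neutral-loss rules then promote a single candidate to MS2-confirmed.")
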