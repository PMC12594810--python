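"""Classify LCP media into jetting regimes and score the published
decision rules against the packaged reference table.

Loads the packaged table of 22 LCP media (viscosity at 0.3 and
75.4 s^-1 plus the jetting outcome observed at a jet-testing station)
and compares the absolute-threshold and viscosity-ratio classifiers
with the observed labels.
"""

from rheojet import (
    classify_absolute,
    classify_ratio,
    concordance_report,
    load_reference_table,
)

records = load_reference_table()
pure_lcp = next(r for r in records if r.additive is None)

# single-medium calls
call = classify_absolute(5.4e5)  # 7.5% MPD medium at 0.3 s^-1
print(f"absolute rule at 0.3 1/s: eta=5.4e5 mPa.s -> {call.label.value}")
call = classify_ratio(5.4e5, pure_lcp.eta_lve)
print(f"ratio rule (ref {pure_lcp.eta_lve:.1e}): ratio="
      f"{5.4e5 / pure_lcp.eta_lve:.3f} -> {call.label.value}")

# how well do the published rules reproduce the observed outcomes?
for method in ("absolute_lve", "ratio", "absolute_jet"):
    rep = concordance_report(records, method)
    print(f"{method:>12}: {rep.n_agree}/{rep.n_total} media agree; "
          f"mismatches: {', '.join(rep.mismatches) or 'none'}")

# absolute_lve and ratio agree with 18/22 and 19/22 observed outcomes;
# the jet-shear thresholds reproduce only a minority and carry a warning.
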