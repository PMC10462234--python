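"""Survival-normalized RGC subclass composition across conditions.

Raw subclass percentages in a post-injury sample are fractions of the
surviving cells; multiplying by the independently measured total survival
rate puts every condition on the pre-injury scale.  The rates used here
(63.8% for injured controls, 85.4% with a neuroprotective receptor
overexpressed) are the kind of values an immunostaining count provides.
"""

import pandas as pd

import retinacomm as rc

samples = [
    rc.SubclassCounts("sham", {"ipRGC": 120, "alphaRGC": 180, "T-RGC": 700},
                      total_survival_rate=1.0),
    rc.SubclassCounts("injured", {"ipRGC": 115, "alphaRGC": 170, "T-RGC": 340},
                      total_survival_rate=0.638),
    rc.SubclassCounts("injured+protected", {"ipRGC": 112, "alphaRGC": 168, "T-RGC": 560},
                      total_survival_rate=0.854),
]

adjusted = pd.DataFrame({s.condition: rc.normalize_by_survival(s) for s in samples})
print(adjusted.round(2))
print("\ncolumn sums (= survival rate x 100):", adjusted.sum().round(1).to_dict())
# Comparing the "injured" column against "sham" row by row now reflects
# true subclass losses, not their share of whatever survived.
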