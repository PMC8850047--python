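"""Small built-in reference tables.

Currently a single dataset: the published drug-likeness/ADMET prediction
panel for ten candidate ginsenosides (triterpenoid saponins), with endpoint
values from ADMETlab-2.0-style predictors.  It is the canonical worked
example for the gate rules: three of the ten compounds (ginsenosides C-Mc,
F2 and Mx) pass every rule, six fail on F20% bioavailability and one —
(20R)-ginsenoside Rh2 — on plasma protein binding.
"""

from __future__ import annotations

import io

import pandas as pd

_REFERENCE_ADMET_CSV = """\
id,druglikeness,pains,f20,ppb,aot,skin_sens
Ginsenoside XVII,0.848,0,0.986,72.66,0,0.005
Ginsenoside C-Mx1,0.854,0,0.981,75.10,0,0.008
NSC308876,0.856,0,0.986,72.90,0,0.005
Ginsenoside F2,0.846,0,0.67,83.91,0,0.015
Ginsenoside Rs2,0.812,0,0.996,60.39,0,0.002
Ginsenoside Rs1,0.804,0,0.995,60.82,0,0.002
Ginsenoside C-Mc,0.818,0,0.608,86.59,0,0.034
Ginsenoside LXXV,0.818,0,0.753,83.36,0,0.023
Ginsenoside Mx,0.764,0,0.655,86.74,0,0.032
(20R)-Ginsenoside Rh2,0.772,0,0.076,94.05,0,0.038
"""


def load_reference_admet_table() -> pd.DataFrame:
    """The ten-ginsenoside reference ADMET panel as a gate-ready table.

    Columns: ``id, druglikeness, pains, f20, ppb, aot, skin_sens``
    (PPB in percent).
    """
    return pd.read_csv(io.StringIO(_REFERENCE_ADMET_CSV))
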