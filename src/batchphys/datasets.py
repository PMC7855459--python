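"""Published reference rates for the C. glutamicum anaplerosis strain panel.

Specific growth rates (µ, 1/h), d-glucose uptake rates (π_GLC,
mmol/gCDW/h) and CO₂ formation rates (π_CO2, mmol/gCDW/h) estimated
from controlled batch bioreactor cultivations of wild-type
C. glutamicum ATCC 13032 and deletion mutants of the anaplerotic node
(PEP carboxylase *ppc*, pyruvate carboxylase *pyc*, PEP carboxykinase
*pck*, malic enzyme *malE*, oxaloacetate decarboxylase *odx*), together
with the instantaneous carbon balance Θ reported alongside them.  The
``theta_reported`` column is the published value; recomputing Θ from
the printed rates is the standard consistency check on the panel.
"""

from __future__ import annotations

import pandas as pd

_PANEL = [
    # strain, mu, sd_mu, pi_glc, sd_pi_glc, pi_co2, sd_pi_co2, theta, sd_theta
    ("WT",              0.45, 0.04, 4.82, 0.25, 6.94, 0.71, 0.82, 0.089),
    ("dpck",            0.38, 0.02, 4.10, 0.14, 5.51, 0.53, 0.81, 0.077),
    ("dppc",            0.45, 0.04, 5.12, 0.24, 7.64, 1.09, 0.79, 0.083),
    ("dpyc",            0.40, 0.02, 4.65, 0.17, 7.43, 0.76, 0.80, 0.072),
    ("dmalE",           0.46, 0.02, 4.88, 0.17, 7.00, 1.00, 0.84, 0.080),
    ("dpck_dmalE",      0.46, 0.04, 4.85, 0.24, 7.27, 0.83, 0.83, 0.087),
    ("dppc_dmalE",      0.43, 0.03, 4.84, 0.25, 6.79, 1.92, 0.79, 0.088),
    ("dpyc_dodx",       0.40, 0.02, 4.38, 0.17, 6.31, 0.99, 0.81, 0.078),
    ("dppc_dpyc_evo",   0.27, 0.01, 3.74, 0.16, 7.40, 0.68, 0.78, 0.070),
]

_COLUMNS = [
    "strain", "mu", "sd_mu", "pi_glc", "sd_pi_glc",
    "pi_co2", "sd_pi_co2", "theta_reported", "sd_theta_reported",
]


def anaplerosis_panel() -> pd.DataFrame:
    """Return the strain panel as a DataFrame indexed by strain label."""
    return pd.DataFrame(_PANEL, columns=_COLUMNS).set_index("strain")
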