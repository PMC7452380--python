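"""Published reference values for worked examples and regression anchors.

Group summaries (n, free-running period τ ± SEM, fit error ± SEM, mean
expression level ± SEM) for Drosophila clock-gene luciferase reporters
recorded at four constant temperatures, as printed in the originating
study: four reporter lines in cultured halteres, one in cultured brains,
and two whole-fly genotypes. These printed means are the inputs to the
package's Q10 / Δτ worked examples; the underlying raw recordings were
never deposited, so per-sample values are not available.

Reporter lines: *plo* and *tim-luc* are transcriptional reporters for
*per* and *tim*; *XLG-luc* and *ptim-TIM-luc* report PER and TIM protein
levels; *8.0-luc* restricts PER-LUC to dorsal brain clock neurons
(recorded in intact flies, alone and in a *Pdf*^01^ background).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_group_table",
    "reference_q10",
    "REFERENCE_DELTA_TAU_H",
]

# genotype, tissue, °C, n, tau_mean, tau_sem, err_mean, err_sem, cps_mean, cps_sem
_ROWS = [
    ("plo", "haltere", 18, 23, 22.8, 0.2, 0.15, 0.01, 377.9, 31.3),
    ("plo", "haltere", 21, 30, 22.9, 0.1, 0.04, 0.01, 302.4, 18.9),
    ("plo", "haltere", 25, 28, 24.2, 0.1, 0.04, 0.01, 385.2, 35.7),
    ("plo", "haltere", 29, 11, 24.4, 0.2, 0.05, 0.01, 190.2, 23.1),
    ("tim-luc", "haltere", 18, 25, 22.1, 0.2, 0.32, 0.03, 505.6, 33.7),
    ("tim-luc", "haltere", 21, 23, 23.0, 0.1, 0.07, 0.01, 705.7, 53.4),
    ("tim-luc", "haltere", 25, 33, 24.6, 0.1, 0.03, 0.01, 1361.8, 85.8),
    ("tim-luc", "haltere", 29, 25, 24.8, 0.1, 0.03, 0.01, 1340.3, 85.5),
    ("XLG-luc", "haltere", 18, 22, 19.9, 0.4, 0.25, 0.03, 115.3, 6.1),
    ("XLG-luc", "haltere", 21, 12, 20.2, 0.3, 0.26, 0.03, 117.4, 9.7),
    ("XLG-luc", "haltere", 25, 28, 21.2, 0.1, 0.07, 0.01, 157.2, 7.2),
    ("XLG-luc", "haltere", 29, 14, 23.4, 0.1, 0.07, 0.01, 149.1, 8.6),
    ("ptim-TIM-luc", "haltere", 18, 27, 21.0, 0.1, 0.17, 0.02, 77.7, 4.2),
    ("ptim-TIM-luc", "haltere", 21, 37, 21.7, 0.1, 0.09, 0.01, 99.2, 5.8),
    ("ptim-TIM-luc", "haltere", 25, 53, 24.0, 0.1, 0.10, 0.01, 112.2, 8.6),
    ("ptim-TIM-luc", "haltere", 29, 67, 25.2, 0.1, 0.04, 0.01, 134.4, 6.9),
    ("ptim-TIM-luc", "brain", 18, 14, 28.6, 0.4, 0.33, 0.02, 184.3, 16.6),
    ("ptim-TIM-luc", "brain", 21, 13, 30.8, 0.6, 0.20, 0.02, 167.7, 18.2),
    ("ptim-TIM-luc", "brain", 25, 14, 30.0, 0.8, 0.30, 0.03, 187.7, 8.1),
    ("ptim-TIM-luc", "brain", 29, 5, 30.0, 1.2, 0.32, 0.06, 324.3, 80.1),
    ("8.0-luc", "whole_fly", 18, 38, 24.8, 0.3, 0.42, 0.03, 85.1, 5.2),
    ("8.0-luc", "whole_fly", 21, 10, 23.9, 0.8, 0.59, 0.04, 89.9, 10.4),
    ("8.0-luc", "whole_fly", 25, 31, 24.5, 0.2, 0.43, 0.03, 71.5, 5.8),
    ("8.0-luc", "whole_fly", 29, 17, 23.2, 0.3, 0.17, 0.02, 40.3, 2.9),
    ("8.0-luc;Pdf01", "whole_fly", 18, 41, 21.7, 0.2, 0.27, 0.03, 23.1, 0.9),
    ("8.0-luc;Pdf01", "whole_fly", 21, 18, 22.7, 0.1, 0.54, 0.03, 17.7, 0.7),
    ("8.0-luc;Pdf01", "whole_fly", 25, 30, 21.7, 0.1, 0.27, 0.03, 20.4, 1.0),
    ("8.0-luc;Pdf01", "whole_fly", 29, 15, 22.5, 0.1, 0.26, 0.03, 15.2, 0.8),
]

_COLUMNS = [
    "genotype",
    "tissue",
    "temperature_c",
    "n",
    "tau_mean_h",
    "tau_sem_h",
    "error_mean",
    "error_sem",
    "cps_mean",
    "cps_sem",
]

#: Q10 values printed alongside each genotype × tissue block (18°C vs 29°C).
_PRINTED_Q10 = {
    ("plo", "haltere"): 0.94,
    ("tim-luc", "haltere"): 0.90,
    ("XLG-luc", "haltere"): 0.86,
    ("ptim-TIM-luc", "haltere"): 0.85,
    ("ptim-TIM-luc", "brain"): 0.96,
    ("8.0-luc", "whole_fly"): 1.06,
    ("8.0-luc;Pdf01", "whole_fly"): 0.97,
}

#: Reported period lengthening (Δτ, hours) from 18°C to 29°C in halteres.
REFERENCE_DELTA_TAU_H = {
    "ptim-TIM-luc": 4.2,
    "XLG-luc": 3.5,
    "tim-luc": 2.7,
    "plo": 1.6,
}


def reference_group_table() -> pd.DataFrame:
    """The published group summaries as a DataFrame (one row per
    genotype × tissue × temperature)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reference_q10() -> dict[tuple[str, str], float]:
    """Printed Q10 per (genotype, tissue), computed between 18 and 29°C."""
    return dict(_PRINTED_Q10)
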