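"""Published PLS-DA prediction tables of the *W. cocos* origin study.

The original study printed, for each validation sample and each of five
variable sets (the full 886-variable window and the CARS / MC-UVE / SPA /
LPG selections), the actual class, the Galtier decision flag, the predicted
value Y_pre and its deviation Y_dev, together with per-column accuracies.
These tables are transcribed here verbatim so the Galtier verdict machinery
can be replayed against them.

Known transcription caveat: two printed rows (FLP-46, 886-variable column;
FLP-05, LPG column) carry (Y_pre, Y_dev) values that are provably
inconsistent with every other printed flag under any rule monotone in the
deviation and the distance to the nearest class code; they are transcribed
as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Printed per-column accuracies (%), keyed by (tissue, variable set).
REFERENCE_ACCURACIES: dict[tuple[str, str], float] = {
    ("BFL", "full"): 84.21,
    ("BFL", "CARS"): 100.0,
    ("BFL", "MCUVE"): 100.0,
    ("BFL", "SPA"): 100.0,
    ("BFL", "LPG"): 100.0,
    ("FLP", "full"): 94.44,
    ("FLP", "CARS"): 94.44,
    ("FLP", "MCUVE"): 100.0,
    ("FLP", "SPA"): 94.44,
    ("FLP", "LPG"): 100.0,
}

#: Number of selected variables per printed column.
REFERENCE_VARIABLE_COUNTS: dict[tuple[str, str], int] = {
    ("BFL", "full"): 886,
    ("BFL", "CARS"): 40,
    ("BFL", "MCUVE"): 95,
    ("BFL", "SPA"): 90,
    ("BFL", "LPG"): 129,
    ("FLP", "full"): 886,
    ("FLP", "CARS"): 20,
    ("FLP", "MCUVE"): 35,
    ("FLP", "SPA"): 30,
    ("FLP", "LPG"): 129,
}


def load_reference_predictions(tissue: str) -> pd.DataFrame:
    """Long-format table: sample_id, method, actual_class, flag, y_pre, y_dev."""
    if tissue not in ("BFL", "FLP"):
        raise ValueError(f"tissue must be BFL or FLP, got {tissue!r}")
    name = f"{tissue.lower()}_reference_predictions.csv"
    with resources.files("nirselect.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)
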