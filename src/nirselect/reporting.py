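"""Run reports and spectra-structure annotation of characteristic variables.

The annotation table maps each characteristic wavenumber to the NIR
overtone/combination band it falls on (C-H, O-H, N-H chemistry of the
triterpene / polysaccharide / protein constituents that differ between the
sclerotium peel and inner part). It is informational only: nothing here
feeds back into selection or classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Spectra-structure assignments of the characteristic variables (cm^-1).
BAND_ASSIGNMENTS: tuple[tuple[float, str], ...] = (
    (4092.21, "C-H aryl vibration in benzene band"),
    (4096.06, "C-H aryl vibration in benzene band"),
    (4123.06, "C-H aryl vibration in benzene band"),
    (4165.49, "C-H aryl vibration in benzene band"),
    (4308.19, "combination of C-H stretch and C-H2 deformation in polysaccharides"),
    (4439.33, "combination of O-H and C-O stretch in glucose"),
    (4485.61, "second overtones of symmetric and asymmetric CH2 bending of the uncoupled vinyl group"),
    (4501.04, "combination of asymmetric N-H stretch and NH2 rocking in urea"),
    (4508.75, "combination of asymmetric N-H stretch and NH2 rocking in urea"),
    (4566.61, "C-H aryl vibration in benzene band"),
    (4570.47, "C-H aryl vibration in benzene band"),
    (4597.46, "CONH2 combination of amide B and amide II modes"),
    (4612.89, "CONH2 of the alpha-helix peptide structure"),
    (4952.30, "combination of O-H stretch and C-H bending"),
    (5079.58, "combination of N-H stretching and N-H bending in aromatic amine"),
    (5230.00, "hydroxyl band"),
    (5233.86, "hydroxyl band"),
    (5303.28, "hydroxyl band"),
    (5634.98, "C-H in methylene"),
    (5685.12, "C-H in methylene"),
    (5866.40, "C-H first overtone stretch in CH3"),
    (5874.11, "C-H in methyl"),
    (5928.11, "C-H in methyl with O-H associated"),
)

#: Lookup tolerance in cm^-1.
ANNOTATION_TOL = 2.0

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BandAnnotation:
    wavenumber: float
    assignment: str


def annotate_bands(wavenumbers: Iterable[float], tol: float = ANNOTATION_TOL) -> list[BandAnnotation]:
    """Nearest-entry lookup into the assignment table, within ``tol`` cm^-1."""
    table_wn = np.array([w for w, _ in BAND_ASSIGNMENTS])
    out = []
    for w in wavenumbers:
        w = float(w)
        i = int(np.argmin(np.abs(table_wn - w)))
        text = BAND_ASSIGNMENTS[i][1] if abs(table_wn[i] - w) <= tol else UNASSIGNED
        out.append(BandAnnotation(wavenumber=w, assignment=text))
    return out


REPORT_SECTIONS = (
    "Preprocessing",
    "Outlier screening",
    "Training/validation split",
    "Variable selection",
    "PLS-DA evaluation",
    "Fisher discriminant model",
    "Leave-one-out validation",
)


def _frame_md(df: pd.DataFrame, max_rows: int = 40) -> str:
    if df is None or len(df) == 0:
        return "_(empty)_"
    shown = df.head(max_rows)
    txt = "```\n" + shown.to_string(float_format=lambda v: f"{v:.4f}") + "\n```"
    if len(df) > max_rows:
        txt += f"\n\n_... {len(df) - max_rows} more rows not shown_"
    return txt


def render_run_report(stages: dict, path: str | Path | None = None) -> str:
    """Assemble a deterministic Markdown run report.

    ``stages`` may provide: preprocess (list of step dicts), outliers
    (OutlierReport-like), split (dict), selection (dict method -> summary),
    evaluation (DataFrame), verdicts (DataFrame), fisher (dict), loo (dict),
    annotations (list of BandAnnotation). Missing stages are flagged as gaps
    rather than failing. No timestamps: identical inputs give identical
    bytes.
    """
    lines: list[str] = ["# nirselect run report", ""]

    def gap(name: str) -> None:
        lines.extend([f"## {name}", "", "_stage missing from this run_", ""])

    if "preprocess" in stages:
        lines.extend(["## Preprocessing", ""])
        for step in stages["preprocess"]:
            params = ", ".join(f"{k}={v}" for k, v in step.items() if k != "step")
            lines.append(f"- {step['step']}" + (f" ({params})" if params else ""))
        lines.append("")
    else:
        gap("Preprocessing")

    if "outliers" in stages:
        rep = stages["outliers"]
        lines.extend(["## Outlier screening", ""])
        removed = getattr(rep, "removed_ids", rep.get("removed_ids") if isinstance(rep, dict) else [])
        lines.append(f"Removed samples: {', '.join(removed) if removed else 'none'}")
        lines.append("")
    else:
        gap("Outlier screening")

    if "split" in stages:
        sp = stages["split"]
        lines.extend(
            [
                "## Training/validation split",
                "",
                f"Training: {sp.get('n_training', '?')} samples; "
                f"validation: {sp.get('n_validation', '?')} samples "
                f"(fraction {sp.get('validation_fraction', '?')}).",
                "",
            ]
        )
    else:
        gap("Training/validation split")

    if "selection" in stages:
        lines.extend(["## Variable selection", ""])
        for method, summary in stages["selection"].items():
            lines.append(f"- **{method}**: {summary}")
        lines.append("")
    else:
        gap("Variable selection")

    if "evaluation" in stages:
        lines.extend(["## PLS-DA evaluation", "", _frame_md(stages["evaluation"]), ""])
        if "verdicts" in stages:
            lines.extend(["### Validation verdicts", "", _frame_md(stages["verdicts"], 120), ""])
    else:
        gap("PLS-DA evaluation")

    if "fisher" in stages:
        fi = stages["fisher"]
        lines.extend(["## Fisher discriminant model", ""])
        lines.append(
            f"Retained variables ({len(fi.get('wavenumbers', []))}): "
            + ", ".join(f"{w:.2f}" for w in fi.get("wavenumbers", []))
        )
        if "resubstitution_accuracy" in fi:
            lines.append(f"\nResubstitution accuracy: {fi['resubstitution_accuracy']:.2f}%")
        if "coefficients" in fi:
            lines.extend(["", _frame_md(fi["coefficients"])])
        lines.append("")
    else:
        gap("Fisher discriminant model")

    if "loo" in stages:
        lo = stages["loo"]
        lines.extend(
            [
                "## Leave-one-out validation",
                "",
                f"Accuracy: {lo['accuracy']:.2f}%",
                "",
                _frame_md(lo.get("confusion")),
                "",
            ]
        )
    else:
        gap("Leave-one-out validation")

    if "annotations" in stages:
        lines.extend(["## Band assignments", ""])
        for ann in stages["annotations"]:
            lines.append(f"- {ann.wavenumber:.2f} cm^-1: {ann.assignment}")
        lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
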