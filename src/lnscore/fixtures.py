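"""Embedded pilot-cohort fixture.

The scoring system was developed on a pilot cohort of eight mice: five
injected with metastasizing (KPN) intestinal-tumor organoids (subjects
1-5) and three with wild-type organoids (subjects A-C).  The published
per-subject score matrix and the histopathology outcomes are embedded
here so the diagnostic-performance tables can be reproduced without any
raw imaging data: subject 5's CEUS analysis failed motion correction on
the control node, so its TTP and WiR are unavailable and its sum score
runs over three parameters; subject 4's left node looked involved on
imaging (score 4/5) but carried no metastasis on pathology.

``REPORTED_PERFORMANCE`` holds the performance table as originally
reported, for cross-checking: the computed replica agrees cell-for-cell
except the TTP PPV upper confidence bound, where the exact interval for
3/4 rounds to 99 while the reported table prints 100 (the same fraction
is printed with a 99 bound elsewhere in that table — a suspected
typographical inconsistency, reported as computed and flagged, not
matched).
"""

from __future__ import annotations

import pandas as pd

from .diagnostics import SUM_THRESHOLDS, report_table
from .scoring import ScoreCard

__all__ = [
    "PILOT_SCORES",
    "PILOT_PATHOLOGY",
    "REPORTED_PERFORMANCE",
    "pilot_scorecards",
    "pilot_report",
    "compare_with_reported",
]

# subject -> {parameter -> 0 | 1 | None (unavailable)}
PILOT_SCORES: dict[str, dict[str, int | None]] = {
    "1": {"volume": 1, "shape": 1, "hilum": 1, "ttp": 1, "wir": 1},
    "2": {"volume": 1, "shape": 1, "hilum": 1, "ttp": 1, "wir": 1},
    "3": {"volume": 1, "shape": 1, "hilum": 1, "ttp": 1, "wir": 1},
    "4": {"volume": 1, "shape": 1, "hilum": 1, "ttp": 1, "wir": 0},
    "5": {"volume": 1, "shape": 1, "hilum": 1, "ttp": None, "wir": None},
    "A": {"volume": 0, "shape": 1, "hilum": 0, "ttp": 0, "wir": 0},
    "B": {"volume": 0, "shape": 0, "hilum": 0, "ttp": 0, "wir": 0},
    "C": {"volume": 0, "shape": 0, "hilum": 0, "ttp": 0, "wir": 0},
}

# histopathology of the tumor-draining (left) node of each subject
PILOT_PATHOLOGY: dict[str, bool] = {
    "1": True, "2": True, "3": True, "4": False, "5": True,
    "A": False, "B": False, "C": False,
}

# performance table as originally reported: variable -> metric -> string
REPORTED_PERFORMANCE: dict[str, dict[str, str]] = {
    "volume": {"specificity": "75 [19-99]", "ppv": "80 [28-99]",
               "npv": "100 [29-100]", "accuracy": "88 [47-100]"},
    "shape": {"specificity": "50 [7-93]", "ppv": "67 [22-96]",
              "npv": "100 [16-100]", "accuracy": "75 [35-97]"},
    "hilum": {"specificity": "75 [19-99]", "ppv": "80 [28-99]",
              "npv": "100 [29-100]", "accuracy": "88 [47-100]"},
    "ttp": {"specificity": "75 [19-99]", "ppv": "75 [19-100]",
            "npv": "100 [29-100]", "accuracy": "86 [42-100]"},
    "wir": {"specificity": "100 [40-100]", "ppv": "100 [29-100]",
            "npv": "100 [40-100]", "accuracy": "100 [59-100]"},
    "sum score 0": {"specificity": "50 [7-93]", "ppv": "67 [22-96]",
                    "npv": "100 [16-100]", "accuracy": "75 [35-97]"},
    "sum score 20": {"specificity": "50 [7-93]", "ppv": "67 [22-96]",
                     "npv": "100 [16-100]", "accuracy": "75 [35-97]"},
    "sum score 40": {"specificity": "75 [19-99]", "ppv": "80 [28-99]",
                     "npv": "100 [29-100]", "accuracy": "88 [47-100]"},
    "sum score 60": {"specificity": "75 [19-99]", "ppv": "80 [28-99]",
                     "npv": "100 [29-100]", "accuracy": "88 [47-100]"},
    "sum score 80": {"specificity": "75 [19-99]", "ppv": "80 [28-99]",
                     "npv": "100 [29-100]", "accuracy": "88 [47-100]"},
    "sum score 100": {"specificity": "100 [40-100]", "ppv": "100 [40-100]",
                      "npv": "100 [40-100]", "accuracy": "100 [63-100]"},
}


def pilot_scorecards() -> list[ScoreCard]:
    """The eight pilot subjects as ScoreCard objects (fixture mode)."""
    return [
        ScoreCard(subject_id=sid, scores=dict(scores))
        for sid, scores in PILOT_SCORES.items()
    ]


def pilot_report(confidence: float = 0.95) -> pd.DataFrame:
    """Full diagnostic-performance replica computed from the fixture."""
    return report_table(pilot_scorecards(), PILOT_PATHOLOGY, confidence)


def compare_with_reported() -> list[dict[str, str]]:
    """Cells where the computed replica differs from the reported table.

    Returns one dict per discrepant cell with the computed and reported
    strings.  Expected content: exactly one cell (TTP PPV upper bound,
    computed 99 vs reported 100).
    """
    df = pilot_report().set_index("variable")
    out = []
    for variable, metrics in REPORTED_PERFORMANCE.items():
        for metric, reported in metrics.items():
            computed = df.loc[variable, metric]
            if computed != reported:
                out.append(
                    {
                        "variable": variable,
                        "metric": metric,
                        "computed": computed,
                        "reported": reported,
                    }
                )
    return out
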