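"""Study-level analysis report: descriptive tables, group comparisons,
ANOVAs, the ischemia assessment and per-segment boxplot figures.

This is the end-to-end pre/post analysis: for each segment the pre-ischemia
group is compared with every post-ischemia time group by pooled t-test, the
stability of each segment over time is screened by one-way ANOVA, and the
ischemic segment gets an AMISD/RMISD assessment with the binary call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import stats as st
from .study import (
    DEFAULT_ISCHEMIA_THRESHOLD,
    POST_LABELS,
    SEGMENTS,
    TIME_LABELS,
    StudyMatrix,
    assess_ischemia,
)

logger = logging.getLogger(__name__)

_TIME_MINUTES = {"post15": 15, "post45": 45, "post75": 75, "post105": 105, "post135": 135}


@dataclass
class StudyReport:
    """All analysis products for one study matrix."""

    descriptives: pd.DataFrame
    comparisons: pd.DataFrame
    anovas: dict[str, st.AnovaResult]
    assessments: dict[str, "object"]
    pre_contrast: st.TTestResult


def comparison_table(
    study: StudyMatrix, segment: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Pre vs each post time for one segment, as a comparison-table frame.

    Columns: comparison, n, mean, sd, p, ci_low, ci_high — the group mean/SD
    are those of the post-time group, the p and CI are for (pre mean − post
    mean) from the pooled two-sample t-test.
    """
    pre = study.select(segment, "pre")
    rows = []
    d_pre = st.describe(pre)
    rows.append(
        {
            "comparison": f"{segment} pre-ischemia",
            "n": d_pre.n, "mean": d_pre.mean, "sd": d_pre.sd,
            "p": float("nan"), "ci_low": float("nan"), "ci_high": float("nan"),
        }
    )
    for label in POST_LABELS:
        post = study.select(segment, label)
        if post.size == 0:
            continue
        d = st.describe(post)
        tt = st.pooled_t_test(pre, post, alpha=alpha)
        rows.append(
            {
                "comparison": f"{segment} {_TIME_MINUTES[label]}' after vessel division",
                "n": d.n, "mean": d.mean, "sd": d.sd,
                "p": tt.p_two_sided, "ci_low": tt.ci_low, "ci_high": tt.ci_high,
            }
        )
    n_tests = len(rows) - 1
    if n_tests > 2:
        logger.info(
            "%d pairwise comparisons reported without multiple-testing "
            "correction (mirrors the original analysis)", n_tests,
        )
    return pd.DataFrame(rows)


def descriptive_table(study: StudyMatrix) -> pd.DataFrame:
    """Per-segment, per-time descriptive summary (n, mean, sd, 95% CI)."""
    rows = []
    for segment in SEGMENTS:
        for label in TIME_LABELS:
            vals = study.select(segment, label)
            if vals.size == 0:
                continue
            if vals.size < 2:
                rows.append(
                    {"segment": segment, "time_label": label, "n": 1,
                     "mean": float(vals[0]), "sd": float("nan"),
                     "ci_low": float("nan"), "ci_high": float("nan")}
                )
                continue
            d = st.describe(vals)
            rows.append(
                {"segment": segment, "time_label": label, "n": d.n,
                 "mean": d.mean, "sd": d.sd, "ci_low": d.ci_low, "ci_high": d.ci_high}
            )
    return pd.DataFrame(rows)


def analyze_study(
    study: StudyMatrix,
    threshold_percent: float = DEFAULT_ISCHEMIA_THRESHOLD,
    alpha: float = 0.05,
    ischemic_segment: str = "left",
) -> StudyReport:
    """Run the full pre/post analysis.

    ANOVA composition per segment: the control segment is screened for
    stability over the *whole* experiment (pre plus all post times); the
    ischemic segment over the post-ischemia period only, since its pre level
    is expected to differ.
    """
    anovas: dict[str, st.AnovaResult] = {}
    for segment in SEGMENTS:
        groups = [study.select(segment, lbl) for lbl in POST_LABELS]
        groups = [g for g in groups if g.size > 0]
        if segment != ischemic_segment:
            pre = study.select(segment, "pre")
            if pre.size:
                groups = [pre] + groups
        anovas[segment] = st.one_way_anova(groups)

    assessments = {
        ischemic_segment: assess_ischemia(study, ischemic_segment, threshold_percent)
    }
    comparisons = pd.concat(
        [comparison_table(study, seg, alpha) for seg in SEGMENTS], ignore_index=True
    )
    pre_contrast = st.pooled_t_test(
        study.select("right", "pre"), study.select("left", "pre"), alpha=alpha
    )
    return StudyReport(
        descriptives=descriptive_table(study),
        comparisons=comparisons,
        anovas=anovas,
        assessments=assessments,
        pre_contrast=pre_contrast,
    )


def write_study_report(
    report: StudyReport, study: StudyMatrix, out_dir: str | Path
) -> dict[str, Path]:
    """Write the report products (CSV/JSON tables plus boxplot figures)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["descriptives"] = out_dir / "descriptives.csv"
    report.descriptives.round(4).to_csv(paths["descriptives"], index=False)

    paths["comparisons"] = out_dir / "comparisons.csv"
    comp = report.comparisons.copy()
    for c in ("mean", "sd", "ci_low", "ci_high"):
        comp[c] = comp[c].round(4)
    comp["p"] = comp["p"].round(3)
    comp.to_csv(paths["comparisons"], index=False)

    paths["anova"] = out_dir / "anova.json"
    with open(paths["anova"], "w") as fh:
        json.dump({seg: a.to_dict() for seg, a in report.anovas.items()}, fh, indent=2)

    paths["assessment"] = out_dir / "assessment.json"
    with open(paths["assessment"], "w") as fh:
        json.dump(
            {
                "pre_contrast": report.pre_contrast.to_dict(),
                **{seg: a.to_dict() for seg, a in report.assessments.items()},
            },
            fh,
            indent=2,
        )

    for segment in SEGMENTS:
        series = []
        labels = []
        for label in TIME_LABELS:
            vals = study.select(segment, label)
            if vals.size:
                series.append(vals)
                labels.append(label)
        if not series:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.boxplot(series, tick_labels=labels)
        ax.set_ylabel("mean ICG saturation (0-255)")
        ax.set_title(f"{segment} colon over time")
        fig.tight_layout()
        p = out_dir / f"boxplot_{segment}.png"
        fig.savefig(p, metadata={"Software": None})
        plt.close(fig)
        paths[f"boxplot_{segment}"] = p
    return paths
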