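"""Study matrices and the AMISD / RMISD ischemia metrics.

A study is a tidy table of mean ICG saturations (0-255 green scale), one row
per (subject, intestinal segment, observation time).  Times are one
pre-ischemia control reading plus five post-ischemia readings taken 15, 45,
75, 105 and 135 minutes after division of the inferior mesenteric artery
arcade.  Missing cells (animal losses) are permitted and are skipped, never
imputed.

The two headline metrics compare a segment's mean saturation before and
after ischemia induction::

    AMISD = MISPreI - MISPostI                     (absolute decrease, points)
    RMISD = (1 - MISPostI / MISPreI) * 100         (relative decrease, %)

where MISPreI averages the per-subject pre-ischemia readings and MISPostI
pools *all* post-ischemia readings across subjects and times with equal
weight.  A relative decrease at or above the threshold (default 32.6%, the
pig-model estimate for complete devascularisation) is classified as
ischemic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import EmptyGroupError, IcgquantError

SEGMENTS = ("right", "left")
TIME_LABELS = ("pre", "post15", "post45", "post75", "post105", "post135")
POST_LABELS = TIME_LABELS[1:]

#: Relative-decrease cutoff (percent) for calling complete tissue ischemia.
#: An experimental estimate from a pig model, not a clinical constant.
DEFAULT_ISCHEMIA_THRESHOLD = 32.6

_COLUMNS = ["subject_id", "segment", "time_label", "saturation"]


@dataclass(frozen=True)
class SegmentObservation:
    """One mean ICG saturation reading for a subject/segment/time cell."""

    subject_id: str
    segment: str
    time_label: str
    saturation: float


class StudyMatrix:
    """Tidy collection of per-subject, per-segment, per-time saturations.

    Wraps a :class:`pandas.DataFrame` with columns
    ``subject_id, segment, time_label, saturation`` and validates on
    construction: known segment/time labels, saturations on the 0-255 scale,
    at most one observation per cell.
    """

    def __init__(self, observations: pd.DataFrame | Iterable[SegmentObservation]):
        if isinstance(observations, pd.DataFrame):
            df = observations.loc[:, _COLUMNS].copy()
        else:
            df = pd.DataFrame(
                [
                    (o.subject_id, o.segment, o.time_label, o.saturation)
                    for o in observations
                ],
                columns=_COLUMNS,
            )
        df["subject_id"] = df["subject_id"].astype(str)
        df["saturation"] = df["saturation"].astype(float)
        bad_seg = set(df["segment"]) - set(SEGMENTS)
        if bad_seg:
            raise ValueError(f"unknown segment labels: {sorted(bad_seg)}")
        bad_time = set(df["time_label"]) - set(TIME_LABELS)
        if bad_time:
            raise ValueError(f"unknown time labels: {sorted(bad_time)}")
        if ((df["saturation"] < 0) | (df["saturation"] > 255)).any():
            raise ValueError("saturations must lie on the 0-255 scale")
        dup = df.duplicated(subset=["subject_id", "segment", "time_label"])
        if dup.any():
            cells = df.loc[dup, ["subject_id", "segment", "time_label"]]
            raise ValueError(f"duplicate observations for cells:\n{cells}")
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying tidy table (copy)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def select(
        self, segment: str | None = None, time_label: str | Iterable[str] | None = None
    ) -> np.ndarray:
        """Saturation values matching the given segment and time label(s)."""
        df = self._df
        if segment is not None:
            df = df[df["segment"] == segment]
        if time_label is not None:
            labels = [time_label] if isinstance(time_label, str) else list(time_label)
            df = df[df["time_label"].isin(labels)]
        return df["saturation"].to_numpy()

    def subjects(self) -> list[str]:
        return sorted(self._df["subject_id"].unique())

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise IcgquantError(f"cannot parse study CSV {path}: {exc}") from exc
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise IcgquantError(
                f"{path}: study CSV lacks required columns {sorted(missing)}"
            )
        return cls(df)


@dataclass(frozen=True)
class IschemiaAssessment:
    """Pre/post comparison of a segment with the binary ischemia call."""

    segment: str
    mis_pre: float
    mis_post: float
    amisd: float
    rmisd_percent: float
    threshold_percent: float
    is_ischemic: bool
    n_pre: int
    n_post: int

    def to_dict(self) -> dict:
        return {
            "segment": self.segment,
            "mis_pre": self.mis_pre,
            "mis_post": self.mis_post,
            "amisd": self.amisd,
            "rmisd_percent": self.rmisd_percent,
            "threshold_percent": self.threshold_percent,
            "is_ischemic": self.is_ischemic,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
        }


def group_mean(study: StudyMatrix, segment: str, time_label: str) -> tuple[float, int]:
    """Arithmetic mean (and n) over subjects for one segment/time cell group."""
    vals = study.select(segment, time_label)
    if vals.size == 0:
        raise EmptyGroupError(f"no observations for segment={segment}, time={time_label}")
    return float(vals.mean()), int(vals.size)


def mis_pre(study: StudyMatrix, segment: str) -> float:
    """Mean ICG saturation of the segment before ischemia induction."""
    return group_mean(study, segment, "pre")[0]


def mis_post(study: StudyMatrix, segment: str) -> float:
    """Mean over *all* post-ischemia readings, pooled across subjects and times.

    Every available reading carries equal weight; this is not a mean of
    per-time means, so subjects with missing late time points contribute
    fewer readings.
    """
    vals = study.select(segment, POST_LABELS)
    if vals.size == 0:
        raise EmptyGroupError(f"no post-ischemia observations for segment={segment}")
    return float(vals.mean())


def amisd(mis_pre_value: float, mis_post_value: float) -> float:
    """Absolute mean ICG saturation decrease (may be negative if signal rose)."""
    return mis_pre_value - mis_post_value


def rmisd(mis_pre_value: float, mis_post_value: float) -> float:
    """Relative mean ICG saturation decrease, in percent of the pre value."""
    if mis_pre_value == 0:
        raise IcgquantError("RMISD undefined: pre-ischemia mean saturation is 0")
    return (1.0 - mis_post_value / mis_pre_value) * 100.0


def classify_ischemia(
    rmisd_percent: float,
    threshold_percent: float = DEFAULT_ISCHEMIA_THRESHOLD,
) -> bool:
    """True iff the relative decrease reaches the threshold (closed cutoff)."""
    if not (0 < threshold_percent <= 100):
        raise ValueError(f"threshold must be in (0, 100], got {threshold_percent}")
    return bool(rmisd_percent >= threshold_percent)


def assess_ischemia(
    study: StudyMatrix,
    segment: str = "left",
    threshold_percent: float = DEFAULT_ISCHEMIA_THRESHOLD,
) -> IschemiaAssessment:
    """Full pre/post assessment of one segment, ending in the binary call."""
    pre = mis_pre(study, segment)
    post = mis_post(study, segment)
    rel = rmisd(pre, post)
    return IschemiaAssessment(
        segment=segment,
        mis_pre=pre,
        mis_post=post,
        amisd=amisd(pre, post),
        rmisd_percent=rel,
        threshold_percent=threshold_percent,
        is_ischemic=classify_ischemia(rel, threshold_percent),
        n_pre=int(study.select(segment, "pre").size),
        n_post=int(study.select(segment, POST_LABELS).size),
    )
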