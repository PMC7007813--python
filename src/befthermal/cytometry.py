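"""Flow-cytometry processing: gating, production metrics, species assignment.

Event tables (forward scatter FSC, side scatter SSC, red fluorescence FL3)
are filtered with three fixed log10 thresholds separating live cells from
debris, converted to community abundance (cells/mL) and total chlorophyll
a (pg/mL, via a log-log calibration from FL3), and decomposed into
per-species abundances with a random-forest classifier trained on
labelled monoculture events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

# log10 thresholds below which events are considered debris, not live cells
FSC_LOG10_MIN = 5.0
SSC_LOG10_MIN = 5.0
FL3_LOG10_MIN = 3.5

CHANNELS = ("fsc", "ssc", "fl3")


@dataclass(frozen=True)
class CalibrationCurve:
    """Log-log map from FL3 to per-cell chlorophyll a (pg).

    log10(chl) = slope * log10(FL3) + intercept.  The default identity
    slope with a configurable intercept is a stand-in; a real instrument
    calibration is supplied via config.
    """

    slope: float = 1.0
    intercept: float = -5.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")

    def chl_per_cell(self, fl3) -> np.ndarray:
        return 10.0 ** (self.slope * np.log10(np.asarray(fl3, float))
                        + self.intercept)


@dataclass
class FilterResult:
    """Gated event table plus bookkeeping of what was removed."""

    events: pd.DataFrame
    n_raw: int
    n_kept: int
    n_nonpositive: int

    @property
    def n_removed(self) -> int:
        return self.n_raw - self.n_kept


def filter_events(events: pd.DataFrame) -> FilterResult:
    """Remove sub-threshold (debris) events.

    An event is kept iff log10(FSC) >= 5 AND log10(SSC) >= 5 AND
    log10(FL3) >= 3.5; boundary events exactly at a threshold are kept
    (the gate removes strictly smaller values).  Events with non-positive
    channel values (log undefined) are dropped and counted separately.
    """
    n_raw = len(events)
    if n_raw == 0:
        return FilterResult(events.copy(), 0, 0, 0)
    ch = events[list(CHANNELS)].to_numpy(float)
    positive = np.all(ch > 0, axis=1)
    n_nonpositive = int((~positive).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.log10(np.where(ch > 0, ch, np.nan))
    keep = positive & (lg[:, 0] >= FSC_LOG10_MIN) \
        & (lg[:, 1] >= SSC_LOG10_MIN) & (lg[:, 2] >= FL3_LOG10_MIN)
    kept = events.loc[keep].reset_index(drop=True)
    return FilterResult(kept, n_raw, int(keep.sum()), n_nonpositive)


@dataclass
class CommunityMeasurement:
    """Per-well production metrics derived from gated events."""

    unit_id: str
    abundance: float       # cells mL^-1
    total_chl: float       # pg chl a mL^-1
    n_events_raw: int
    n_events_kept: int


def events_to_metrics(
    events: pd.DataFrame,
    cal: CalibrationCurve,
    volume_uL: float = 20.0,
    dilution: float = 1.0,
    unit_id: str = "",
    prefiltered: bool = False,
) -> CommunityMeasurement:
    """Convert an event table to abundance and total chlorophyll per mL.

    abundance = kept events / (counted volume in mL) * dilution;
    total chlorophyll sums the calibrated per-event chlorophyll and scales
    the same way.
    """
    if volume_uL <= 0:
        raise ValueError("counted volume must be > 0")
    if dilution <= 0:
        raise ValueError("dilution factor must be > 0")
    if prefiltered:
        fr = FilterResult(events, len(events), len(events), 0)
    else:
        fr = filter_events(events)
    volume_mL = volume_uL / 1000.0
    scale = dilution / volume_mL
    if fr.n_kept == 0:
        return CommunityMeasurement(unit_id, 0.0, 0.0, fr.n_raw, 0)
    chl = cal.chl_per_cell(fr.events["fl3"])
    return CommunityMeasurement(
        unit_id=unit_id,
        abundance=fr.n_kept * scale,
        total_chl=float(chl.sum()) * scale,
        n_events_raw=fr.n_raw,
        n_events_kept=fr.n_kept,
    )


# ---------------------------------------------------------------------------
# Species assignment
# ---------------------------------------------------------------------------

def _features(events: pd.DataFrame) -> np.ndarray:
    return np.log10(events[list(CHANNELS)].to_numpy(float))


@dataclass
class SpeciesClassifier:
    """Random forest on (log10 FSC, log10 SSC, log10 FL3) features."""

    model: RandomForestClassifier
    classes: Sequence[str]
    per_class_accuracy: pd.Series   # out-of-bag accuracy per species

    def predict(self, events: pd.DataFrame) -> np.ndarray:
        return self.model.predict(_features(events))

    def mean_margin(self, events: pd.DataFrame) -> float:
        """Mean max-class-probability over events (assignment confidence)."""
        proba = self.model.predict_proba(_features(events))
        return float(proba.max(axis=1).mean())


def train_species_classifier(
    monoculture_events: Mapping[str, pd.DataFrame],
    expected_species: Optional[Sequence[str]] = None,
    n_estimators: int = 200,
    random_state: int = 0,
) -> SpeciesClassifier:
    """Train a species classifier from labelled (gated) monoculture tables.

    ``monoculture_events`` maps species_id -> event table from that
    species' monoculture wells at the relevant temperature.  Events are
    gated before training.  Out-of-bag accuracy is reported per class.
    Raises if any expected species has no events.
    """
    if expected_species is not None:
        absent = sorted(set(expected_species) - set(monoculture_events))
        if absent:
            raise ValueError(f"no monoculture events for species: {absent}")
    feats, labels = [], []
    empty = []
    for sid, ev in monoculture_events.items():
        gated = filter_events(ev).events
        if len(gated) == 0:
            empty.append(sid)
            continue
        feats.append(_features(gated))
        labels.extend([sid] * len(gated))
    if empty:
        raise ValueError(f"no gated events for species: {sorted(empty)}")
    X = np.vstack(feats)
    y = np.asarray(labels)
    rf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=random_state,
        n_jobs=1,
    )
    rf.fit(X, y)
    # per-class OOB accuracy
    oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
    acc = pd.Series(
        {sid: float(np.mean(oob_pred[y == sid] == sid))
         for sid in rf.classes_}
    )
    return SpeciesClassifier(model=rf, classes=list(rf.classes_),
                             per_class_accuracy=acc)


@dataclass
class SpeciesAssignment:
    """Decomposition of one community's abundance across species."""

    abundances: pd.Series    # cells mL^-1 per species, sums to total
    mean_margin: float
    flagged: bool            # low classifier confidence
    n_events: int


def assign_species(
    community_events: pd.DataFrame,
    classifier: SpeciesClassifier,
    volume_uL: float = 20.0,
    dilution: float = 1.0,
    margin_threshold: float = 0.5,
    prefiltered: bool = False,
) -> SpeciesAssignment:
    """Split a community's (gated) events among species.

    Each kept event is assigned to exactly one species, so the per-species
    abundances sum to the community abundance exactly.  Communities whose
    mean max-class-probability falls below ``margin_threshold`` are
    flagged as low-confidence rather than dropped.
    """
    events = community_events if prefiltered \
        else filter_events(community_events).events
    zero = pd.Series(0.0, index=list(classifier.classes))
    if len(events) == 0:
        return SpeciesAssignment(zero, np.nan, False, 0)
    pred = classifier.predict(events)
    counts = pd.Series(pred).value_counts()
    scale = dilution / (volume_uL / 1000.0)
    abund = zero.add(counts.astype(float) * scale, fill_value=0.0)
    margin = classifier.mean_margin(events)
    return SpeciesAssignment(
        abundances=abund, mean_margin=margin,
        flagged=margin < margin_threshold, n_events=len(events),
    )


def load_events_csv(path, column_map: Optional[Mapping[str, str]] = None
                    ) -> pd.DataFrame:
    """Read an events CSV, renaming instrument channel columns.

    ``column_map`` maps instrument names (e.g. "FSC-A") to the canonical
    lowercase names; by default the common Accuri-style headers are
    recognised.
    """
    frame = pd.read_csv(path)
    default = {"FSC-A": "fsc", "SSC-A": "ssc", "FL3-A": "fl3",
               "FSC": "fsc", "SSC": "ssc", "FL3": "fl3"}
    mapping = dict(default)
    if column_map:
        mapping.update(column_map)
    frame = frame.rename(columns=mapping)
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(f"events table missing channels: {missing}")
    return frame
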