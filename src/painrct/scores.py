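"""Secondary-outcome scoring: PIPP-R, tachycardia rule, STAI-State, ICC.

PIPP-R (Premature Infant Pain Profile – Revised) sums seven indicators,
each banded 0–3: heart-rate increase, oxygen-saturation decrease, three
facial actions (brow bulge, eye squeeze, nasolabial furrow, banded by the
fraction of the observation window they occupy), gestational age and
behavioural state. The two contextual indicators (gestational age,
behavioural state) are added only when the physiological + facial
subtotal is positive, so a baby showing no pain response scores 0
regardless of age or state. The banding table ships as a CSV data file
(``painrct/data/pipp_r_rubric.csv``) so the rubric can be amended without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import pingouin as pg

from painrct.errors import InvalidArgumentError, MissingDataError

__all__ = [
    "BEHAVIOURAL_STATES",
    "STAI_REVERSE_ITEMS",
    "PippRObservation",
    "PippRScore",
    "TachycardiaRule",
    "load_rubric",
    "pipp_r",
    "detect_tachycardia",
    "stai_state_score",
    "icc",
]

BEHAVIOURAL_STATES = ("active_awake", "quiet_awake", "active_asleep", "quiet_asleep")

#: 1-based indices of the anxiety-absent (reverse-scored) items on the
#: 20-item State scale, Form Y.
STAI_REVERSE_ITEMS = frozenset({1, 2, 5, 8, 10, 11, 15, 16, 19, 20})

FACIAL_ACTIONS = ("brow_bulge", "eye_squeeze", "nasolabial_furrow")


@dataclass(frozen=True)
class PippRObservation:
    """Everything the PIPP-R rubric consumes for one event."""

    gestational_age: float            # weeks
    behavioural_state: str            # one of BEHAVIOURAL_STATES
    baseline_hr: float                # bpm, pre-event baseline mean
    max_hr_post: float                # bpm
    baseline_spo2: float              # percent
    min_spo2_post: float              # percent
    brow_bulge_duration: float        # seconds within the observation window
    eye_squeeze_duration: float
    nasolabial_furrow_duration: float
    observation_window: float = 30.0


@dataclass(frozen=True)
class PippRScore:
    subscores: dict                   # indicator -> points (0-3)
    subtotal_physio_facial: int
    total: int


@dataclass(frozen=True)
class TachycardiaRule:
    """Threshold-crossing rule around the lance."""

    threshold_bpm: float = 160.0
    baseline_window_s: float = 15.0
    post_window_s: float = 30.0

    def __post_init__(self) -> None:
        if self.threshold_bpm <= 0 or self.baseline_window_s <= 0 or self.post_window_s <= 0:
            raise InvalidArgumentError("tachycardia rule parameters must be positive")


_RUBRIC_CACHE: pd.DataFrame | None = None


def load_rubric() -> pd.DataFrame:
    """The packaged PIPP-R banding table."""
    global _RUBRIC_CACHE
    if _RUBRIC_CACHE is None:
        with resources.files("painrct.data").joinpath("pipp_r_rubric.csv").open() as fh:
            _RUBRIC_CACHE = pd.read_csv(fh)
    return _RUBRIC_CACHE


def _band_points(rubric: pd.DataFrame, indicator: str, value: float) -> int:
    rows = rubric[rubric.indicator == indicator]
    if rows.empty:
        raise MissingDataError(f"rubric has no indicator {indicator!r}")
    for _, r in rows.iterrows():
        lo, hi = float(r.lower), float(r.upper)
        if lo <= value < hi or (np.isinf(hi) and value >= lo):
            return int(r.points)
    raise InvalidArgumentError(f"{indicator} value {value} outside all rubric bands")


def _categorical_points(rubric: pd.DataFrame, indicator: str, level: str) -> int:
    rows = rubric[(rubric.indicator == indicator) & (rubric.band == level)]
    if rows.empty:
        raise InvalidArgumentError(f"unknown {indicator} level {level!r}")
    return int(rows.iloc[0].points)


def pipp_r(obs: PippRObservation) -> PippRScore:
    """Score one observation with the packaged PIPP-R rubric.

    Physiological changes are (max post HR − baseline HR) and
    (baseline SpO2 − min post SpO2), clipped below at 0; facial actions
    are banded by the fraction of the observation window they occupy.
    Missing (NaN) components raise — scores are never imputed.
    """
    fields = {
        "gestational_age": obs.gestational_age,
        "baseline_hr": obs.baseline_hr,
        "max_hr_post": obs.max_hr_post,
        "baseline_spo2": obs.baseline_spo2,
        "min_spo2_post": obs.min_spo2_post,
        "brow_bulge_duration": obs.brow_bulge_duration,
        "eye_squeeze_duration": obs.eye_squeeze_duration,
        "nasolabial_furrow_duration": obs.nasolabial_furrow_duration,
    }
    for name, v in fields.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDataError(f"PIPP-R component {name} is missing")
    if obs.behavioural_state not in BEHAVIOURAL_STATES:
        raise InvalidArgumentError(
            f"behavioural_state must be one of {BEHAVIOURAL_STATES}, got {obs.behavioural_state!r}"
        )
    win = obs.observation_window
    if win <= 0:
        raise InvalidArgumentError("observation_window must be positive")
    for action in FACIAL_ACTIONS:
        d = fields[f"{action}_duration"]
        if not 0 <= d <= win + 1e-9:
            raise InvalidArgumentError(f"{action} duration {d} outside [0, {win}] s")

    rubric = load_rubric()
    sub: dict[str, int] = {}
    sub["hr_change"] = _band_points(
        rubric, "hr_increase", max(0.0, obs.max_hr_post - obs.baseline_hr)
    )
    sub["spo2_change"] = _band_points(
        rubric, "spo2_decrease", max(0.0, obs.baseline_spo2 - obs.min_spo2_post)
    )
    for action in FACIAL_ACTIONS:
        frac = min(fields[f"{action}_duration"] / win, 1.0)
        sub[action] = _band_points(rubric, "facial_fraction", frac)
    subtotal = sum(sub.values())

    sub["gestational_age"] = _band_points(rubric, "gestational_age", obs.gestational_age)
    sub["behavioural_state"] = _categorical_points(
        rubric, "behavioural_state", obs.behavioural_state
    )
    total = subtotal
    if subtotal > 0:
        total += sub["gestational_age"] + sub["behavioural_state"]
    return PippRScore(subscores=sub, subtotal_physio_facial=subtotal, total=total)


def detect_tachycardia(trace, rule: TachycardiaRule | None = None) -> bool:
    """Apply the trial's tachycardia definition to a vital-sign trace.

    True iff no heart-rate sample exceeds the threshold in the pre-lance
    baseline window ``[-15, 0)`` s, and at least one sample reaches it
    (>=) in the post-lance window ``(0, +30]`` s. Both boundary wordings
    admit equality at the threshold.
    """
    rule = rule or TachycardiaRule()
    t = np.asarray(trace.time, dtype=float) - float(trace.lance_time)
    hr = np.asarray(trace.heart_rate, dtype=float)
    if t.min() > -rule.baseline_window_s + 1e-9 or t.max() < rule.post_window_s - 1e-9:
        raise InvalidArgumentError(
            f"trace covers [{t.min():.1f}, {t.max():.1f}] s around the lance; "
            f"need [-{rule.baseline_window_s:g}, +{rule.post_window_s:g}] s"
        )
    baseline = hr[(t >= -rule.baseline_window_s) & (t < 0)]
    post = hr[(t > 0) & (t <= rule.post_window_s)]
    if baseline.size == 0 or post.size == 0:
        raise InvalidArgumentError("no heart-rate samples in the baseline or post window")
    baseline_ok = not np.any(baseline > rule.threshold_bpm)
    post_crossed = bool(np.any(post >= rule.threshold_bpm))
    return baseline_ok and post_crossed


def stai_state_score(items, reverse_items=STAI_REVERSE_ITEMS) -> int:
    """Total a 20-item State-anxiety sheet (each item 1–4; total 20–80).

    ``items`` are the raw responses in item order; the anxiety-absent
    items in ``reverse_items`` (1-based positions) are reverse-keyed
    (1<->4, 2<->3) before summing.
    """
    if hasattr(items, "items") and not callable(items.items):
        items = items.items  # accept a StaiResponse-like record
    arr = np.asarray(items, dtype=float)
    if arr.shape != (20,):
        raise InvalidArgumentError(f"expected exactly 20 items, got shape {arr.shape}")
    if np.any(np.isnan(arr)) or np.any((arr < 1) | (arr > 4)) or np.any(arr != np.round(arr)):
        raise InvalidArgumentError("items must be integers in [1, 4]")
    scored = arr.copy()
    idx = np.array(sorted(reverse_items), dtype=int) - 1
    if np.any((idx < 0) | (idx >= 20)):
        raise InvalidArgumentError("reverse_items must be 1-based positions in 1..20")
    scored[idx] = 5 - scored[idx]
    return int(scored.sum())


def icc(ratings: np.ndarray, form: str = "agreement") -> tuple[float, tuple[float, float]]:
    """Intraclass correlation for a subjects x raters matrix.

    Two-way model, single measure: ``form="agreement"`` gives ICC(A,1)
    (absolute agreement), ``form="consistency"`` gives ICC(C,1). Returns
    the estimate and its F-distribution 95 % CI.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2:
        raise InvalidArgumentError("ratings must be a 2-D subjects x raters matrix")
    n_subj, n_raters = mat.shape
    if n_raters < 2 or n_subj < 5:
        raise InvalidArgumentError("need >= 2 raters and >= 5 subjects")
    if np.any(np.isnan(mat)):
        raise MissingDataError("ratings matrix contains missing cells")
    if form not in ("agreement", "consistency"):
        raise InvalidArgumentError(f"form must be agreement or consistency, got {form!r}")

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "score": mat.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate MSE at ICC=1
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
    wanted = "ICC(A,1)" if form == "agreement" else "ICC(C,1)"
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.set_index("Type").loc[wanted]
    lo, hi = (float(v) for v in row[ci_col])
    return float(row["ICC"]), (lo, hi)
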