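"""Dataset directory layout: plain-text round-trip of a full trial dataset.

    <dir>/
      config.yaml          generation config
      participants.csv
      allocations.csv      id, arm, imbalance_*, p_used
      compliance.csv
      vitals/<id>.csv      time, heart_rate, spo2
      vitals_events.csv    id, lance_time, sham_time
      facial.csv           id, event, the three durations, observation_window
      stai.csv             id, respondent, stage, item01..item20
      epochs_meta.json     sampling rate, window, stimulus index, channels
      epochs/<id>_<event>.csv   long format: channel, time_s, microvolts
      groundtruth.json     true parameters, per-participant magnitudes,
                           missingness sets, seed

Epochs use a documented long-format CSV container rather than a binary
EEG format so datasets stay text-only and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from painrct.config import TrialConfig
from painrct.epochs import EEGEpoch
from painrct.errors import ParseError
from painrct.synthetic import (
    OUTCOMES,
    ComplianceRecord,
    FacialAnnotation,
    GroundTruth,
    ParticipantRecord,
    StaiResponse,
    TrialDataset,
    VitalTrace,
)

__all__ = ["write_dataset", "read_dataset"]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas parser errors carry the row number
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def write_dataset(dataset: TrialDataset, out_dir) -> Path:
    out = Path(out_dir)
    (out / "vitals").mkdir(parents=True, exist_ok=True)
    (out / "epochs").mkdir(parents=True, exist_ok=True)

    (out / "config.yaml").write_text(dataset.config.to_yaml())
    dataset.participants_frame().to_csv(out / "participants.csv", index=False)
    dataset.allocations.to_csv(out / "allocations.csv", index=False)

    pd.DataFrame(
        [
            {
                "id": pid,
                "arm": r.arm,
                "stroke_start": r.stroke_start,
                "stroke_end": r.stroke_end,
                "delay_to_lance": r.delay_to_lance,
                "compliant": r.compliant,
            }
            for pid, r in dataset.compliance.items()
        ]
    ).to_csv(out / "compliance.csv", index=False)

    events = []
    for pid, tr in dataset.vitals.items():
        pd.DataFrame(
            {"time": tr.time, "heart_rate": tr.heart_rate, "spo2": tr.spo2}
        ).to_csv(out / "vitals" / f"{pid}.csv", index=False)
        events.append({"id": pid, "lance_time": tr.lance_time, "sham_time": tr.sham_time})
    pd.DataFrame(events).to_csv(out / "vitals_events.csv", index=False)

    pd.DataFrame(
        [
            {
                "id": pid,
                "event": event,
                "brow_bulge_duration": f.brow_bulge_duration,
                "eye_squeeze_duration": f.eye_squeeze_duration,
                "nasolabial_furrow_duration": f.nasolabial_furrow_duration,
                "observation_window": f.observation_window,
            }
            for pid, by_event in dataset.facial.items()
            for event, f in by_event.items()
        ]
    ).to_csv(out / "facial.csv", index=False)

    stai_rows = []
    for pid, sheets in dataset.stai.items():
        for s in sheets:
            row = {"id": pid, "respondent": s.respondent, "stage": s.stage}
            row.update({f"item{i + 1:02d}": int(v) for i, v in enumerate(s.items)})
            stai_rows.append(row)
    pd.DataFrame(stai_rows).to_csv(out / "stai.csv", index=False)

    any_epoch: EEGEpoch = next(iter(dataset.epochs.values()))["lance"]
    meta = {
        "sampling_rate": any_epoch.sampling_rate,
        "epoch_window": list(any_epoch.epoch_window),
        "stimulus_index": any_epoch.stimulus_index,
        "channels": list(any_epoch.channels),
    }
    (out / "epochs_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for pid, by_event in dataset.epochs.items():
        for event, ep in by_event.items():
            n_ch, n_s = ep.data.shape
            pd.DataFrame(
                {
                    "channel": np.repeat(ep.channels, n_s),
                    "time_s": np.tile(ep.times, n_ch),
                    "microvolts": ep.data.ravel(),
                }
            ).to_csv(out / "epochs" / f"{pid}_{event}.csv", index=False)

    gt = dataset.ground_truth
    (out / "groundtruth.json").write_text(
        json.dumps(
            {
                "seed": dataset.seed,
                "complier_effect": gt.complier_effect,
                "control_magnitude_mean": gt.control_magnitude_mean,
                "control_magnitude_sd": gt.control_magnitude_sd,
                "compliance_rate": gt.compliance_rate,
                "tachycardia_base_rate": gt.tachycardia_base_rate,
                "true_magnitudes": gt.true_magnitudes,
                "missing": {k: sorted(v) for k, v in dataset.missing.items()},
            },
            indent=1,
            sort_keys=True,
        )
    )
    return out


def read_dataset(in_dir) -> TrialDataset:
    src = Path(in_dir)
    config = TrialConfig.from_yaml((src / "config.yaml").read_text())

    pdf = _read_csv(
        src / "participants.csv",
        [
            "id",
            "gestational_age_at_birth",
            "postnatal_age",
            "sex",
            "site",
            "blood_test_reason",
            "stroking_parent",
            "behavioural_state_baseline",
            "prior_painful_procedures",
        ],
    )
    participants = [
        ParticipantRecord(
            id=str(r.id),
            gestational_age_at_birth=float(r.gestational_age_at_birth),
            postnatal_age=int(r.postnatal_age),
            sex=str(r.sex),
            site=str(r.site),
            blood_test_reason=str(r.blood_test_reason),
            stroking_parent=str(r.stroking_parent),
            behavioural_state_baseline=str(r.behavioural_state_baseline),
            prior_painful_procedures=int(r.prior_painful_procedures),
        )
        for r in pdf.itertuples()
    ]

    allocations = _read_csv(
        src / "allocations.csv",
        ["id", "arm", "imbalance_intervention", "imbalance_control", "p_used"],
    )

    cdf = _read_csv(
        src / "compliance.csv",
        ["id", "arm", "stroke_start", "stroke_end", "delay_to_lance", "compliant"],
    )
    compliance = {
        str(r.id): ComplianceRecord(
            arm=str(r.arm),
            stroke_start=float(r.stroke_start),
            stroke_end=float(r.stroke_end),
            delay_to_lance=float(r.delay_to_lance),
            compliant=bool(r.compliant),
        )
        for r in cdf.itertuples()
    }

    edf = _read_csv(src / "vitals_events.csv", ["id", "lance_time", "sham_time"])
    vitals = {}
    for r in edf.itertuples():
        vdf = _read_csv(src / "vitals" / f"{r.id}.csv", ["time", "heart_rate", "spo2"])
        vitals[str(r.id)] = VitalTrace(
            time=vdf.time.to_numpy(),
            heart_rate=vdf.heart_rate.to_numpy(),
            spo2=vdf.spo2.to_numpy(),
            lance_time=float(r.lance_time),
            sham_time=float(r.sham_time),
        )

    fdf = _read_csv(
        src / "facial.csv",
        [
            "id",
            "event",
            "brow_bulge_duration",
            "eye_squeeze_duration",
            "nasolabial_furrow_duration",
            "observation_window",
        ],
    )
    facial: dict = {}
    for r in fdf.itertuples():
        facial.setdefault(str(r.id), {})[str(r.event)] = FacialAnnotation(
            brow_bulge_duration=float(r.brow_bulge_duration),
            eye_squeeze_duration=float(r.eye_squeeze_duration),
            nasolabial_furrow_duration=float(r.nasolabial_furrow_duration),
            observation_window=float(r.observation_window),
        )

    sdf = _read_csv(src / "stai.csv", ["id", "respondent", "stage", "item01"])
    item_cols = [f"item{i + 1:02d}" for i in range(20)]
    missing_items = [c for c in item_cols if c not in sdf.columns]
    if missing_items:
        raise ParseError(f"{src / 'stai.csv'}: missing column(s) {missing_items}")
    stai: dict = {}
    for r in sdf.itertuples():
        stai.setdefault(str(r.id), []).append(
            StaiResponse(
                respondent=str(r.respondent),
                stage=str(r.stage),
                items=np.array([getattr(r, c) for c in item_cols], dtype=int),
            )
        )

    try:
        meta = json.loads((src / "epochs_meta.json").read_text())
    except Exception as exc:
        raise ParseError(f"{src / 'epochs_meta.json'}: {exc}") from exc
    channels = tuple(meta["channels"])
    epochs: dict = {}
    for pid in (str(p.id) for p in participants):
        epochs[pid] = {}
        for event in ("lance", "sham"):
            path = src / "epochs" / f"{pid}_{event}.csv"
            df = _read_csv(path, ["channel", "time_s", "microvolts"])
            n_s = len(df) // len(channels)
            if n_s * len(channels) != len(df):
                raise ParseError(
                    f"{path}: {len(df)} rows is not a multiple of {len(channels)} channels"
                )
            data = np.empty((len(channels), n_s))
            for i, ch in enumerate(channels):
                block = df[df.channel == ch]
                if len(block) != n_s:
                    raise ParseError(f"{path}: channel {ch} has {len(block)} rows, expected {n_s}")
                data[i] = block.microvolts.to_numpy()
            epochs[pid][event] = EEGEpoch(
                sampling_rate=float(meta["sampling_rate"]),
                channels=channels,
                data=data,
                epoch_window=tuple(meta["epoch_window"]),
                stimulus_index=int(meta["stimulus_index"]),
                event_kind=event,
            )

    try:
        gtj = json.loads((src / "groundtruth.json").read_text())
    except Exception as exc:
        raise ParseError(f"{src / 'groundtruth.json'}: {exc}") from exc
    gt = GroundTruth(
        complier_effect=gtj["complier_effect"],
        control_magnitude_mean=gtj["control_magnitude_mean"],
        control_magnitude_sd=gtj["control_magnitude_sd"],
        compliance_rate=gtj["compliance_rate"],
        tachycardia_base_rate=gtj["tachycardia_base_rate"],
        true_magnitudes={str(k): float(v) for k, v in gtj["true_magnitudes"].items()},
    )
    missing = {o: set(gtj.get("missing", {}).get(o, [])) for o in OUTCOMES}

    return TrialDataset(
        participants=participants,
        allocations=allocations,
        compliance=compliance,
        epochs=epochs,
        vitals=vitals,
        facial=facial,
        stai=stai,
        ground_truth=gt,
        seed=int(gtj["seed"]),
        config=config,
        missing=missing,
    )
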