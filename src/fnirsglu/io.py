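"""Plain-text serialization of cohorts and result tables.

Dialect: a long intensity CSV (subject_id, state, time_s, channel,
wavelength_nm, intensity), a glucose CSV (subject_id, state, time_s,
glucose_mmol_per_l), a metadata JSON sidecar (sampling rate, geometry,
seed, config echo) and a parallel ground-truth CSV set (true glucose
curve, coupling coefficients, artifact events).  Numbers are written with
17 significant digits so write→read→write is byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FASTING, GLUCOSE, WAVELENGTHS_NM, SyntheticConfig
from .errors import DataError
from .synthetic import Cohort, GroundTruth, RawRecording, SubjectRecord

FLOAT_FMT = "%.17g"

INTENSITY_COLUMNS = ["subject_id", "state", "time_s", "channel",
                     "wavelength_nm", "intensity"]
GLUCOSE_COLUMNS = ["subject_id", "state", "time_s", "glucose_mmol_per_l"]


def _recording_frame(rec: RawRecording) -> pd.DataFrame:
    T, C, W = rec.intensity.shape
    times = np.repeat(rec.times, C * W)
    channels = np.tile(np.repeat(np.arange(1, C + 1), W), T)
    wavelengths = np.tile(np.asarray(rec.wavelengths_nm), T * C)
    return pd.DataFrame({
        "subject_id": rec.subject_id,
        "state": np.repeat(np.asarray(rec.state_labels, dtype=object), C * W),
        "time_s": times,
        "channel": channels,
        "wavelength_nm": wavelengths,
        "intensity": rec.intensity.ravel(),
    })


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write the cohort to `outdir`; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    refs = []
    truth_glucose = []
    truth_coupling = []
    truth_events = []
    for sub in cohort:
        frames.append(_recording_frame(sub.fasting))
        frames.append(_recording_frame(sub.glucose))
        refs.append(sub.glucose_refs)
        if sub.truth is not None:
            truth_glucose.append(pd.DataFrame({
                "subject_id": sub.subject_id,
                "time_s": sub.truth.times,
                "glucose_mmol_per_l": sub.truth.glucose}))
            truth_coupling.append(pd.DataFrame({
                "subject_id": sub.subject_id,
                "channel": np.arange(1, sub.truth.betas.size + 1),
                "beta_um_per_mmol_l": sub.truth.betas}))
            truth_events.append(pd.DataFrame(sub.truth.events or [],
                                             columns=["channel", "time_s",
                                                      "kind", "magnitude"])
                                .assign(subject_id=sub.subject_id))
    paths = {
        "intensity": outdir / "intensity.csv",
        "glucose": outdir / "glucose.csv",
        "metadata": outdir / "metadata.json",
    }
    pd.concat(frames, ignore_index=True).to_csv(
        paths["intensity"], index=False, float_format=FLOAT_FMT)
    pd.concat(refs, ignore_index=True).to_csv(
        paths["glucose"], index=False, float_format=FLOAT_FMT)
    geometry = cohort.subjects[0].fasting.geometry if cohort.subjects else []
    meta = {
        "sampling_rate_hz": cohort.config.sampling_rate,
        "wavelengths_nm": list(WAVELENGTHS_NM),
        "geometry": geometry,
        "seed": cohort.config.rng_seed,
        "config": cohort.config.to_dict(),
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    if truth_glucose:
        paths["truth_glucose"] = outdir / "truth_glucose.csv"
        pd.concat(truth_glucose, ignore_index=True).to_csv(
            paths["truth_glucose"], index=False, float_format=FLOAT_FMT)
        paths["truth_coupling"] = outdir / "truth_coupling.csv"
        pd.concat(truth_coupling, ignore_index=True).to_csv(
            paths["truth_coupling"], index=False, float_format=FLOAT_FMT)
        paths["truth_events"] = outdir / "truth_events.csv"
        pd.concat(truth_events, ignore_index=True).to_csv(
            paths["truth_events"], index=False, float_format=FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def _require_columns(df: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} missing column(s): {', '.join(missing)}")


def read_cohort(indir) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (or user-supplied CSVs
    in the same dialect).  Ground-truth hemodynamic arrays are not part of
    the on-disk dialect; the true glucose curve and coupling table are
    restored when present."""
    indir = Path(indir)
    meta_path = indir / "metadata.json"
    if not meta_path.exists():
        raise DataError(f"missing metadata.json in {indir}")
    meta = json.loads(meta_path.read_text())
    config = SyntheticConfig.from_dict(meta["config"])

    intensity = pd.read_csv(indir / "intensity.csv", float_precision="round_trip")
    _require_columns(intensity, INTENSITY_COLUMNS, "intensity.csv")
    if intensity.empty:
        raise DataError("empty cohort: intensity.csv has no rows")
    glucose = pd.read_csv(indir / "glucose.csv", float_precision="round_trip")
    _require_columns(glucose, GLUCOSE_COLUMNS, "glucose.csv")

    tg_path = indir / "truth_glucose.csv"
    truth_glucose = pd.read_csv(tg_path, float_precision="round_trip") if tg_path.exists() else None
    tc_path = indir / "truth_coupling.csv"
    truth_coupling = pd.read_csv(tc_path, float_precision="round_trip") if tc_path.exists() else None
    te_path = indir / "truth_events.csv"
    truth_events = pd.read_csv(te_path, float_precision="round_trip") if te_path.exists() else None

    fs = float(meta["sampling_rate_hz"])
    geometry = meta.get("geometry", [])
    wavelengths = tuple(meta.get("wavelengths_nm", WAVELENGTHS_NM))
    subjects = []
    for sid, sgrp in intensity.groupby("subject_id", sort=True):
        recs = {}
        for state in (FASTING, GLUCOSE):
            grp = sgrp[sgrp["state"] == state]
            if grp.empty:
                raise DataError(f"subject {sid} missing state '{state}'")
            piv = grp.pivot_table(index="time_s", columns=["channel", "wavelength_nm"],
                                  values="intensity", sort=True)
            times = piv.index.to_numpy(dtype=float)
            channels = sorted(grp["channel"].unique())
            arr = np.empty((times.size, len(channels), 2))
            for ci, c in enumerate(channels):
                for wi, wl in enumerate(wavelengths):
                    arr[:, ci, wi] = piv[(c, wl)].to_numpy(dtype=float)
            recs[state] = RawRecording(str(sid), state, times, arr, fs,
                                       geometry, wavelengths_nm=wavelengths)
        refs = glucose[glucose["subject_id"] == sid].reset_index(drop=True)
        if refs.empty:
            raise DataError(f"subject {sid} has no reference glucose samples")
        t_lo = recs[FASTING].times.min()
        t_hi = recs[GLUCOSE].times.max()
        ref_t = refs["time_s"].to_numpy(dtype=float)
        if ref_t.min() > t_hi or ref_t.max() < t_lo:
            raise DataError(
                f"subject {sid}: glucose reference times "
                f"[{ref_t.min():g}, {ref_t.max():g}] s do not overlap the "
                f"intensity time base [{t_lo:g}, {t_hi:g}] s")
        truth = None
        if truth_glucose is not None:
            tg = truth_glucose[truth_glucose["subject_id"] == sid]
            betas = np.zeros(recs[FASTING].n_channels)
            if truth_coupling is not None:
                tc = truth_coupling[truth_coupling["subject_id"] == sid]
                betas[tc["channel"].to_numpy(dtype=int) - 1] = \
                    tc["beta_um_per_mmol_l"].to_numpy(dtype=float)
            events = []
            if truth_events is not None:
                events = truth_events[truth_events["subject_id"] == sid] \
                    .drop(columns="subject_id").to_dict("records")
            t = tg["time_s"].to_numpy(dtype=float)
            g = tg["glucose_mmol_per_l"].to_numpy(dtype=float)
            n_f = int(round(config.fasting_duration * fs))
            fast_level = float(g[:n_f].mean()) if n_f <= g.size else float(g.mean())
            truth = GroundTruth(times=t, glucose=g, dhbo=None, dhbr=None,
                                betas=betas, fasting_level=fast_level,
                                events=events)
        subjects.append(SubjectRecord(str(sid), recs[FASTING], recs[GLUCOSE],
                                      refs, truth))
    return Cohort(config=config, subjects=subjects)


def write_hemo_csv(hemos, path) -> None:
    """HemoTimeSeries set → long CSV (subject_id, state, time_s, channel,
    dhbo_um, dhbr_um)."""
    frames = []
    for h in hemos:
        T, C = h.dhbo.shape
        frames.append(pd.DataFrame({
            "subject_id": h.subject_id,
            "state": np.repeat(np.asarray(h.state_labels, dtype=object), C),
            "time_s": np.repeat(h.times, C),
            "channel": np.tile(np.arange(1, C + 1), T),
            "dhbo_um": h.dhbo.ravel(),
            "dhbr_um": h.dhbr.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
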